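family	seed
# Representative broadly conserved mouse microRNA families (seed = mature bases 2-8).
# This list is an editable input: replace it with a full family table as needed.
let-7-5p	GAGGUAG
miR-1-3p	GGAAUGU
miR-7-5p	GGAAGAC
miR-9-5p	CUUUGGU
miR-15-5p	AGCAGCA
miR-17-5p	AAAGUGC
miR-19-3p	GUGCAAA
miR-21-5p	AGCUUAU
miR-22-3p	AGCUGCC
miR-23-3p	UCACAUU
miR-24-3p	GGCUCAG
miR-25-3p	AUUGCAC
miR-26-5p	UCAAGUA
miR-27-3p	UCACAGU
miR-29-3p	AGCACCA
miR-30-5p	GUAAACA
miR-34-5p	GGCAGUG
miR-101-3p	ACAGUAC
miR-124-3p	AAGGCAC
miR-125-5p	CCCUGAG
miR-128-3p	CACAGUG
miR-130-3p	AGUGCAA
miR-133-3p	UUGGUCC
miR-138-5p	GCUGGUG
miR-181-5p	ACAUUCA
miR-204-5p	UCCCUUU
miR-218-5p	UGUGCUU
miR-221-3p	GCUACAU
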