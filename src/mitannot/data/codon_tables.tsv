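# NCBI genetic-code (translation table) start/stop codon sets, transcribed from
# the NCBI taxonomy genetic-code standard (tables are referenced by their NCBI
# numbers). Columns: table_id, name, start_codons (comma-sep), stop_codons.
1	Standard	ATG,CTG,TTG	TAA,TAG,TGA
2	Vertebrate Mitochondrial	ATA,ATC,ATG,ATT,GTG	AGA,AGG,TAA,TAG
3	Yeast Mitochondrial	ATA,ATG,GTG	TAA,TAG
4	Mold Mitochondrial	ATA,ATC,ATG,ATT,CTG,GTG,TTA,TTG	TAA,TAG
5	Invertebrate Mitochondrial	ATA,ATC,ATG,ATT,GTG,TTG	TAA,TAG
9	Echinoderm Mitochondrial	ATG,GTG	TAA,TAG
13	Ascidian Mitochondrial	ATA,ATG,GTG,TTG	TAA,TAG
14	Alternative Flatworm Mitochondrial	ATG	TAG
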