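name	set_id	set_size	overlap	overlap_genes	fdr_p
Regulation of growth	GO:0040008	887	8	PPARG;BCL2;PTEN;GHR;INS;CXCL12;TGFBR2;EP300	0.00028
Response to estrogen	GO:0043627	155	5	PPARG;TGFBR2;EP300;TNFRSF11B;BCL2	0.00028
Leukocyte activation	GO:0045321	991	8	BCL2;INS;CHI3L1;CFD;CXCL12;LTF;TGFBR2;EP300	0.00028
Positive regulation of growth	GO:0045927	354	6	INS;BCL2;CXCL12;TGFBR2;EP300;GHR	0.00028
Response to nutrient levels	GO:0031667	730	7	PPARG;BCL2;PTEN;GHR;TNFRSF11B;INS;TGFBR2	0.00052
Response to extracellular stimulus	GO:0009991	761	7	PPARG;BCL2;PTEN;GHR;TNFRSF11B;INS;TGFBR2	0.00052
Regulation of developmental growth	GO:0048638	445	6	BCL2;PTEN;CXCL12;GHR;TGFBR2;EP300	0.00052
Response to glucose	GO:0009749	219	5	INS;BCL2;PTEN;TGFBR2;EP300	0.00052
Response to alcohol	GO:0097305	460	6	PPARG;BCL2;PTEN;GHR;TGFBR2;EP300	0.00052
Response to hexose	GO:0009746	227	5	INS;BCL2;PTEN;TGFBR2;EP300	0.00052
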