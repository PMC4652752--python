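##gff-version 3
##sequence-region chromosome 1 4640000
# Dual-origin E. coli MG1655-derived model chromosome (4.64 Mbp).
# oriZ is the oriC sequence relocated to 0.344 Mbp; oriC sits at 3.923 Mbp.
# ter and rrn coordinates are approximate literature values rounded to 1 kb;
# only their polarity/orientation semantics are contractual.
chromosome	replichore	origin	3923001	3923001	.	.	.	ID=oriC;Name=oriC
chromosome	replichore	origin	344001	344001	.	.	.	ID=oriZ;Name=oriZ
chromosome	replichore	ter	1341001	1341001	.	.	.	ID=terA;Name=terA;block=counterclockwise;efficiency=1
chromosome	replichore	ter	1682001	1682001	.	.	.	ID=terB;Name=terB;block=clockwise;efficiency=1
chromosome	replichore	ter	1609001	1609001	.	.	.	ID=terC;Name=terC;block=clockwise;efficiency=1
chromosome	replichore	ter	1279001	1279001	.	.	.	ID=terD;Name=terD;block=counterclockwise;efficiency=1
chromosome	replichore	ter	1246001	1246001	.	.	.	ID=terE;Name=terE;block=counterclockwise;efficiency=1
chromosome	replichore	ter	2313001	2313001	.	.	.	ID=terF;Name=terF;block=clockwise;efficiency=1
chromosome	replichore	ter	2376001	2376001	.	.	.	ID=terG;Name=terG;block=clockwise;efficiency=1
chromosome	replichore	ter	685001	685001	.	.	.	ID=terH;Name=terH;block=counterclockwise;efficiency=1
chromosome	replichore	ter	1125001	1125001	.	.	.	ID=terI;Name=terI;block=counterclockwise;efficiency=1
chromosome	replichore	ter	2976001	2976001	.	.	.	ID=terJ;Name=terJ;block=clockwise;efficiency=1
chromosome	replichore	rrn	229001	235000	.	+	.	ID=rrnH;Name=rrnH;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	rrn	2724001	2730000	.	-	.	ID=rrnG;Name=rrnG;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	rrn	3418001	3424000	.	-	.	ID=rrnD;Name=rrnD;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	rrn	3941001	3947000	.	+	.	ID=rrnC;Name=rrnC;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	rrn	4035001	4041000	.	+	.	ID=rrnA;Name=rrnA;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	rrn	4166001	4172000	.	+	.	ID=rrnB;Name=rrnB;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	rrn	4208001	4214000	.	+	.	ID=rrnE;Name=rrnE;head_on_factor=0.25;codirectional_factor=0.9
chromosome	replichore	dif	1589001	1589001	.	.	.	ID=dif;Name=dif
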