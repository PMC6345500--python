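# Brain-Grid white-matter structure table: 34 entries (5 midline, 14
# bilateral tract names, and the vertical SLF segment encoded once with
# hemisphere-pooled cells to match the published 34-structure inventory).
# provenance: "reported" = the entry carries at least one cell association
# stated in the source study's results or case descriptions (remaining cells
# are geometric estimates from standard MNI tract anatomy);
# "geometric-estimate" = all cells estimated from standard MNI tract anatomy.
name	hemisphere	category	cells	provenance
CC-genu	midline	commissural	A2C2S1;A3C2S1;A2C2S2;A3C2S2	reported
CC-body	midline	commissural	A2C1S2;A3C1S2;A2C2S2;A3C2S2;A2C1S3;A3C1S3	geometric-estimate
CC-splenium	midline	commissural	A2C2S3;A3C2S3	geometric-estimate
AC	midline	commissural	A2C2S2;A3C2S2;A2C3S2;A3C3S2	reported
Fo	midline	commissural	A2C2S2;A3C2S2;A2C2S3;A3C2S3;A2C3S3;A3C3S3	geometric-estimate
IC	R	projection	A2C2S2;A2C3S2;A2C2S3	geometric-estimate
IC	L	projection	A3C2S2;A3C3S2;A3C2S3	geometric-estimate
ExC	R	projection	A1C2S2;A2C2S2	reported
ExC	L	projection	A4C2S2;A3C2S2	reported
CST	R	projection	A1C1S2;A2C1S2;A2C1S3;A2C2S2;A2C2S3;A2C3S2	geometric-estimate
CST	L	projection	A4C1S2;A3C1S2;A3C1S3;A3C2S2;A3C2S3;A3C3S2	geometric-estimate
OR	R	projection	A1C2S3;A2C2S3;A1C2S4;A2C2S4	geometric-estimate
OR	L	projection	A4C2S3;A3C2S3;A4C2S4;A3C2S4	geometric-estimate
ATR	R	projection	A2C2S1;A2C2S2	reported
ATR	L	projection	A3C2S1;A3C2S2	reported
Ci	R	associative	A2C1S1;A2C2S1;A2C1S2;A2C2S2;A2C1S3;A2C2S3	reported
Ci	L	associative	A3C1S1;A3C2S1;A3C1S2;A3C2S2;A3C1S3;A3C2S3	reported
ILF	R	associative	A1C3S2;A1C3S3;A1C3S4;A1C2S4	geometric-estimate
ILF	L	associative	A4C3S2;A4C3S3;A4C3S4;A4C2S4	geometric-estimate
MLF	R	associative	A1C2S2;A1C2S3;A1C3S2;A1C3S3	geometric-estimate
MLF	L	associative	A4C2S2;A4C2S3;A4C3S2;A4C3S3	reported
IFOF	R	associative	A2C2S1;A2C2S2;A2C2S3;A2C2S4;A2C3S3	reported
IFOF	L	associative	A3C2S1;A3C2S2;A3C2S3;A3C2S4;A3C3S3	reported
UF	R	associative	A2C2S2;A2C3S2;A1C3S2	reported
UF	L	associative	A3C2S2;A3C3S2;A4C3S2	reported
FAT	R	associative	A1C1S1;A2C1S1;A1C2S1;A2C2S1;A1C2S2	reported
FAT	L	associative	A4C1S1;A3C1S1;A4C2S1;A3C2S1;A4C2S2	geometric-estimate
VOF	R	associative	A1C2S4;A1C3S4	geometric-estimate
VOF	L	associative	A4C2S4;A4C3S4	geometric-estimate
SLF-h	R	associative	A1C1S2;A1C1S3;A1C2S2;A1C2S3	reported
SLF-h	L	associative	A4C1S2;A4C1S3;A4C2S2;A4C2S3	geometric-estimate
SLF-v	midline	associative	A1C2S3;A1C3S3;A4C2S3;A4C3S3	geometric-estimate
AF	R	associative	A1C2S2;A1C2S3;A1C3S2;A1C3S3	reported
AF	L	associative	A4C2S2;A4C2S3;A4C3S2;A4C3S3	geometric-estimate
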