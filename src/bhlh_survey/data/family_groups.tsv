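family	group
ASCa	A
ASCb	A
MyoD	A
E12/E47	A
Ngn	A
NeuroD	A
Atonal	A
Mist	A
Beta3	A
Oligo	A
Net	A
Mesp	A
Twist	A
Paraxis	A
MyoRa	A
MyoRb	A
Hand	A
PTFa	A
PTFb	A
SCL	A
NSCL	A
Delilah	A
SRC	B
FIGα	B
Myc	B
Mad	B
Mnt	B
Max	B
USF	B
MITF	B
SREBP	B
AP4	B
MLX	B
TF4	B
Clock	C
ARNT	C
Bmal	C
Sim	C
AHR	C
Trh	C
HIF	C
Emc	D
Hey	E
H/E(spl)	E
COE	F
Orphan	orphan
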