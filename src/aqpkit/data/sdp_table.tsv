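# Specificity-determining positions (SDP1-SDP9) for six non-aqua substrates.
# role=consensus rows give the allowed residue set per position (slash-separated);
# role=member rows give one aquaporin's observed residues in that substrate context.
# Transcription note: member labels printed with a colon ("PruavPIP1:1",
# "PruavPIP1:2", "PruavPIP1:3") are normalized to semicolons.
role	substrate	aquaporin	sdp1	sdp2	sdp3	sdp4	sdp5	sdp6	sdp7	sdp8	sdp9
consensus	ammonia	-	F/T	K/L/N/V	F/T	V/L/T	A	D/S	A/H/L	E/P/S	A/R/T
member	ammonia	PruavTIP2;1	T	L	I	L	A	T	H	P	V
consensus	boric_acid	-	T/V	I/V	H/I	P	E	I/L	I/L/T	A/T	A/G/K/P
member	boric_acid	PruavPIP1;1	T	I	H	P	E	L	L	T	P
member	boric_acid	PruavPIP1;2	T	I	H	P	E	L	L	T	P
member	boric_acid	PruavPIP1;3	T	I	H	P	E	L	L	T	P
member	boric_acid	PruavPIP2;1	T	I	H	P	E	I	L	T	P
member	boric_acid	PruavPIP2;2	T	I	H	P	E	I	L	T	P
member	boric_acid	PruavPIP2;3	T	I	H	P	E	I	L	T	P
member	boric_acid	PruavPIP2;4	T	I	H	P	E	I	L	T	P
member	boric_acid	PruavNIP1;1	V	I	H	P	E	L	M	A	P
member	boric_acid	PruavNIP2;1	V	I	H	P	E	I	I	A	P
member	boric_acid	PruavNIP4;1	V	I	H	P	E	I	F	A	P
member	boric_acid	PruavNIP4;2	V	I	H	P	E	L	F	A	P
member	boric_acid	PruavNIP5;1	V	I	H	P	E	V	L	A	P
member	boric_acid	PruavNIP5;2	V	I	H	P	E	L	L	A	P
member	boric_acid	PruavNIP6;1	V	I	H	P	E	L	L	A	E
member	boric_acid	PruavNIP7;1	I	I	H	P	E	L	L	T	P
member	boric_acid	PruavXIP2;1	T	I	H	P	E	I	T	T	V
consensus	co2	-	I/L/V	I	C	A	I/V	D	W	D	W
member	co2	PruavPIP1;1	V	I	T	A	I	D	W	D	W
member	co2	PruavPIP1;3	V	I	T	A	I	D	W	D	W
member	co2	PruavPIP2;2	V	I	S	A	V	D	W	D	W
consensus	h2o2	-	A/S	A/G	L/V	A/F/L/T/V	I/L/V	H/I/L/Q	F/Y	A/V	P
member	h2o2	PruavNIP2;1	S	A	L	L	V	I	Y	V	P
member	h2o2	PruavNIP4;1	S	A	L	L	V	L	Y	A	P
member	h2o2	PruavNIP5;1	S	A	L	V	I	L	Y	V	P
member	h2o2	PruavPIP1;1	A	G	V	F	I	H	F	V	P
member	h2o2	PruavPIP1;2	A	G	V	F	I	H	F	V	P
member	h2o2	PruavPIP1;3	A	G	V	F	I	H	F	V	P
member	h2o2	PruavPIP2;1	A	G	V	F	I	Q	F	V	P
member	h2o2	PruavPIP2;2	A	G	V	F	I	Q	F	L	P
member	h2o2	PruavPIP2;3	A	G	V	F	I	Q	F	V	P
member	h2o2	PruavPIP2;4	A	G	V	I	I	Q	F	V	P
member	h2o2	PruavTIP1;1	S	A	L	A	I	H	Y	A	P
member	h2o2	PruavTIP1;3	A	A	L	V	I	H	Y	V	P
member	h2o2	PruavTIP2;1	A	A	L	V	I	N	Y	V	P
member	h2o2	PruavTIP2;2	S	A	L	V	I	N	Y	V	P
member	h2o2	PruavTIP3;1	A	A	L	V	I	H	Y	V	P
member	h2o2	PruavTIP5;1	S	A	L	T	I	Q	Y	V	P
member	h2o2	PruavXIP2;1	A	G	L	V	V	H	F	V	P
consensus	silicic_acid	-	C/S	F/Y	A/E/L	H/R/Y	G	K/N/T	R	E/S/T	A/K/P/T
member	silicic_acid	PruavNIP2;1	S	F	V	H	G	N	R	S	N
consensus	urea	-	H	P	F/I/L/T	A/C/F/L	L/M	A/G/P	G/S	G/S	N
member	urea	PruavNIP1;1	H	P	I	A	L	P	G	S	N
member	urea	PruavNIP2;1	H	P	L	A	M	P	G	S	N
member	urea	PruavNIP5;1	H	P	I	A	L	P	G	S	N
member	urea	PruavNIP5;2	H	P	I	A	L	P	G	S	N
member	urea	PruavPIP1;1	H	P	F	F	L	P	G	G	N
member	urea	PruavPIP1;2	H	P	F	F	L	P	G	G	N
member	urea	PruavPIP1;3	H	P	F	F	L	P	G	G	N
member	urea	PruavPIP2;1	H	P	F	F	L	P	G	G	N
member	urea	PruavPIP2;2	H	P	F	F	L	P	G	G	N
member	urea	PruavPIP2;3	H	P	F	F	L	P	G	G	N
member	urea	PruavPIP2;4	H	P	F	F	L	P	G	G	N
member	urea	PruavTIP1;1	H	P	F	F	L	A	G	S	N
member	urea	PruavTIP1;2	H	P	F	F	L	A	G	S	N
member	urea	PruavTIP1;3	H	P	F	A	L	P	G	S	N
member	urea	PruavTIP2;1	H	P	F	A	L	P	G	S	N
member	urea	PruavTIP2;2	H	P	L	A	L	P	G	S	N
member	urea	PruavTIP3;1	H	P	F	L	L	P	G	S	N
member	urea	PruavTIP4;1	H	P	L	L	L	A	G	S	N
member	urea	PruavTIP5;1	H	P	F	A	L	P	G	S	N
member	urea	PruavXIP1;1	H	L	F	A	V	G	G	G	N
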