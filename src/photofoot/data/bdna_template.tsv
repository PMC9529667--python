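# Synthetic idealized B-form-like nucleotide atom template (local frame, Å).
# Hand-built cylindrical placement approximating fiber B-DNA radii: backbone
# phosphate at ~8.9 Å, sugar carbons 5.9-8.3 Å, pyrimidine C5/C6 at ~3.7-4.2 Å
# with a 1.34 Å C5-C6 bond. Used only by the synthetic helix generator; not
# taken from any experimental structure.
# applies: all = every residue; pyrimidine = C/T residues only.
atom	x	y	z	applies
P	-0.171	8.908	2.080	all
OP1	-1.117	9.807	2.400	all
OP2	0.888	9.057	3.120	all
O5'	-0.967	7.992	1.330	all
C5'	-2.052	7.991	0.670	all
C4'	-2.608	7.117	-0.020	all
O4'	-1.939	6.507	-0.890	all
C3'	-3.276	7.189	-0.630	all
O3'	-2.995	7.719	-1.850	all
C2'	-3.585	6.129	-1.290	all
C1'	-2.684	5.243	-1.460	all
C6	-2.245	3.525	-1.210	pyrimidine
C5	-0.945	3.825	-1.270	pyrimidine
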