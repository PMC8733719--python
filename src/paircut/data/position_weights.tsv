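# Position-weight table for the default on-target activity scorer.
# offset: position relative to the PAM start on the protospacer strand
#   (negative offsets index protospacer bases, -1 adjacent to the PAM;
#    offset 0 is the PAM variable base N of NGG).
# weight: additive log-odds contribution when `base` occupies `offset`.
offset	base	weight
-19	G	0.20
-19	C	-0.10
-16	C	0.20
-14	A	0.10
-10	G	0.10
-10	T	-0.10
-6	C	0.10
-5	G	0.20
-5	T	-0.20
-4	A	0.10
-4	T	-0.30
-3	C	0.30
-3	G	-0.10
-3	T	-0.20
-2	C	0.20
-2	T	-0.20
-1	G	0.50
-1	C	0.10
-1	A	-0.10
-1	T	-0.40
0	C	0.25
0	G	0.05
0	T	-0.15
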