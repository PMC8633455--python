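pair	AU	UA	GC	CG	GU	UG
AU	-1.1	-1.1	-2.2	-2.2	-0.8	-0.8
UA	-1.1	-1.1	-2.2	-2.2	-0.8	-0.8
GC	-2.2	-2.2	-3.3	-3.3	-1.4	-1.4
CG	-2.2	-2.2	-3.3	-3.3	-1.4	-1.4
GU	-0.8	-0.8	-1.4	-1.4	-0.5	-0.5
UG	-0.8	-0.8	-1.4	-1.4	-0.5	-0.5
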