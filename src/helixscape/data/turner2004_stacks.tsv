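pair5	pair3	dg_centikcal
CG	CG	-330
CG	GC	-240
CG	GU	-140
CG	UG	-210
CG	AU	-210
CG	UA	-210
GC	CG	-340
GC	GC	-330
GC	GU	-150
GC	UG	-250
GC	AU	-240
GC	UA	-220
GU	CG	-250
GU	GC	-210
GU	GU	-50
GU	UG	130
GU	AU	-130
GU	UA	-140
UG	CG	-150
UG	GC	-140
UG	GU	30
UG	UG	-50
UG	AU	-100
UG	UA	-60
AU	CG	-220
AU	GC	-210
AU	GU	-60
AU	UG	-140
AU	AU	-90
AU	UA	-110
UA	CG	-240
UA	GC	-210
UA	GU	-100
UA	UG	-130
UA	AU	-130
UA	UA	-90
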