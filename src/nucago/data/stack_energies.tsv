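pair5p	pair3p	delta_g
AU	AU	-0.93
AU	UA	-1.10
AU	CG	-2.24
AU	GC	-2.08
AU	GU	-1.20
AU	UG	-1.20
UA	AU	-1.33
UA	UA	-0.93
UA	CG	-2.35
UA	GC	-2.11
UA	GU	-1.20
UA	UG	-1.20
CG	AU	-2.11
CG	UA	-2.08
CG	CG	-3.26
CG	GC	-2.36
CG	GU	-1.20
CG	UG	-1.20
GC	AU	-2.35
GC	UA	-2.24
GC	CG	-3.42
GC	GC	-3.26
GC	GU	-1.20
GC	UG	-1.20
GU	AU	-1.20
GU	UA	-1.20
GU	CG	-1.20
GU	GC	-1.20
GU	GU	-0.30
GU	UG	-0.30
UG	AU	-1.20
UG	UA	-1.20
UG	CG	-1.20
UG	GC	-1.20
UG	GU	-0.30
UG	UG	-0.30
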