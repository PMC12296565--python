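# Diagnostic key: marker, 1-based reference column, expected state, tier, label.
# trnL-trnF refinement states and the auxiliary cluster loci follow the
# synthetic reference-alignment convention bundled with the package.
marker	position	state	tier	label
matK	249	C	origin	Chinese mainland
matK	435	G	species	A. sinensis
matK	684	T	species	A. sinensis
trnL-trnF	173	G	refine	Chinese mainland
trnL-trnF	183	T	refine	Indonesia
trnL-trnF	200	A	refine	Indochina
matK	58	A	cluster	Chinese cluster
matK	124	G	cluster	Chinese cluster
matK	232	C	cluster	Malesian cluster
matK	261	T	cluster	Malesian cluster
matK	338	G	cluster	Indochina cluster
matK	373	A	cluster	Indochina cluster
matK	559	C	cluster	Indochina cluster
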