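# synthetic MITAB-lite fixture: first two columns are interactor IDs; rest is ignored
uniprotkb:P14867	uniprotkb:P27824	psi-mi:"MI:0018"(two hybrid)	score:0.9
uniprotkb:P28472	uniprotkb:P14867	psi-mi:"MI:0018"(two hybrid)	score:0.5
uniprotkb:P28335	uniprotkb:Q99996	psi-mi:"MI:0006"(anti bait coip)	score:0.7
uniprotkb:P27824	uniprotkb:P14867	psi-mi:"MI:0018"(two hybrid)	score:0.9
uniprotkb:P14867	uniprotkb:P14867	psi-mi:"MI:0018"(two hybrid)	score:0.1
uniprotkb:XXXXX	uniprotkb:P27824	psi-mi:"MI:0018"(two hybrid)	score:0.2
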