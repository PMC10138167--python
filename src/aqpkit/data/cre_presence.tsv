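# Promoter cis-element presence matrix (1 = at least one instance within the
# 2000 bp upstream window) for the 28-member roster, reconstructed from the
# published per-element gene lists. The wound lists name genes with at least
# one of WRE3/WUN; both columns are marked for those genes (documented choice).
gene	ARE	WRE3	WUN	STRE	LTR	MBS	DRE	AT-rich	TC-rich
PruavNIP1;1	1	0	0	0	1	1	0	1	0
PruavNIP2;1	1	0	0	0	0	0	0	1	0
PruavNIP4;1	1	1	1	1	0	0	0	1	1
PruavNIP4;2	1	1	1	1	1	1	1	1	0
PruavNIP5;1	1	1	1	0	1	1	1	0	1
PruavNIP5;2	1	0	0	0	1	1	0	1	0
PruavNIP6;1	0	1	1	1	0	1	0	1	0
PruavNIP7;1	1	1	1	1	1	1	0	0	1
PruavPIP1;1	1	1	1	1	0	1	0	1	0
PruavPIP1;2	1	1	1	0	1	1	1	0	0
PruavPIP1;3	1	1	1	1	1	0	0	0	0
PruavPIP2;1	0	1	1	1	1	0	1	0	0
PruavPIP2;2	1	1	1	1	0	1	0	0	0
PruavPIP2;3	1	1	1	1	1	0	0	0	0
PruavPIP2;4	1	1	1	1	0	0	0	0	0
PruavSIP1;1	1	1	1	1	1	1	1	0	0
PruavSIP1;2	1	1	1	1	0	1	0	0	0
PruavSIP2;1	1	0	0	1	0	1	0	0	1
PruavTIP1;1	0	0	0	1	1	0	1	0	0
PruavTIP1;2	1	1	1	1	1	0	1	1	1
PruavTIP1;3	1	0	0	1	1	1	0	0	0
PruavTIP2;1	0	1	1	1	0	1	0	0	0
PruavTIP2;2	0	1	1	1	1	0	1	1	0
PruavTIP3;1	1	0	0	0	1	1	0	0	0
PruavTIP4;1	1	1	1	1	1	1	0	0	0
PruavTIP5;1	1	1	1	1	1	0	0	0	0
PruavXIP1;1	1	1	1	0	1	1	1	0	0
PruavXIP2;1	1	1	1	0	1	1	0	0	0
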