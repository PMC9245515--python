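# COL1A1a (zebrafish) 3-hydroxyproline sites and their conservation status
# against the human and mouse heart COL1A1 3-HyP catalogs. Positions are
# full-length zebrafish COL1A1a coordinates; "conserved" = also 3-hydroxylated
# at the aligned position in both human and mouse heart ECM, "novel" =
# zebrafish-specific.
position	status
176	conserved
551	conserved
755	conserved
800	conserved
869	conserved
881	conserved
911	conserved
1103	conserved
1106	conserved
1148	conserved
188	novel
317	novel
401	novel
443	novel
446	novel
623	novel
707	novel
854	novel
878	novel
980	novel
992	novel
1034	novel
1166	novel
1169	novel
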