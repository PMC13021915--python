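# Default four-level gating hierarchy.
#
# Each [[rule]] gives a label, the marker-positivity pattern that earns it
# ("all" = every listed marker positive, "any" = at least one positive,
# "none" = every listed marker negative) and a priority; among matching
# rules of a level the highest priority wins.  The tokens "@lineage" and
# "@functional" expand to the panel's marker lists of that role.
#
# Level-1 priority order (immune > endothelial > epithelial > fibroblast >
# functional) resolves multi-lineage co-expression in favour of immune
# identity, so infiltrating immune cells keep their immune label and the
# co-expressed compartment is recorded at level 3 instead.

[options]
# Marker read out for the "transcriptional" functional state.
transcriptional_marker = "pSTAT3"

[level3]
epithelial = ["Ecad", "EGFR", "PanCK"]
endothelial = ["CD31", "Podoplanin"]
fibroblast = ["CD90", "aSMA", "FSP1"]

[level4]
proliferation = ["Ki67", "pERK"]
apoptosis = ["BNIP3"]
autophagy = ["Caveolin"]
pro-inflammatory = ["pNFkB"]
migration = ["IntegrinB1"]
transcriptional = ["pSTAT3"]

# ---- Level 1: five basic types -------------------------------------
[[rule]]
level = 1
label = "immune"
any = ["CD68", "CD20", "CD4", "CD8a", "FoxP3", "CD56", "CD11c"]
priority = 60

[[rule]]
level = 1
label = "endothelial"
any = ["CD31", "Podoplanin"]
priority = 50

[[rule]]
level = 1
label = "epithelial"
all = ["Ecad", "EGFR"]
priority = 40

[[rule]]
level = 1
label = "epithelial"
any = ["PanCK"]
priority = 35

[[rule]]
level = 1
label = "fibroblast"
any = ["CD90", "aSMA", "FSP1"]
priority = 30

# lineage-negative but functionally active cells
[[rule]]
level = 1
label = "functional"
none = ["@lineage"]
any = ["@functional"]
priority = 10

# ---- Level 2: immune subtypes (parent = immune) --------------------
[[rule]]
level = 2
label = "Treg"
parent = "immune"
all = ["CD4", "FoxP3"]
priority = 100

[[rule]]
level = 2
label = "exhausted T"
parent = "immune"
all = ["PD1"]
any = ["CD4", "CD8a"]
priority = 90

[[rule]]
level = 2
label = "BnT"
parent = "immune"
all = ["CD20"]
any = ["CD4", "CD8a"]
priority = 80

[[rule]]
level = 2
label = "M2"
parent = "immune"
all = ["CD68", "CD163"]
priority = 70

[[rule]]
level = 2
label = "macrophage"
parent = "immune"
all = ["CD68"]
priority = 60

[[rule]]
level = 2
label = "B"
parent = "immune"
all = ["CD20"]
priority = 50

[[rule]]
level = 2
label = "CD4 T"
parent = "immune"
all = ["CD4"]
priority = 40

[[rule]]
level = 2
label = "CD8 T"
parent = "immune"
all = ["CD8a"]
priority = 30

[[rule]]
level = 2
label = "NK"
parent = "immune"
all = ["CD56"]
priority = 20

[[rule]]
level = 2
label = "DC"
parent = "immune"
all = ["CD11c"]
priority = 10
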