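# Default biointeraction term dictionary: common molecular-interaction
# verbs in base/-s/-ed inflections plus the nominal form where natural.
# Editable configuration; one term per line, matched case-insensitively.
activate
activates
activated
activation
induce
induces
induced
induction
inhibit
inhibits
inhibited
inhibition
bind
binds
bound
binding
interact
interacts
interacted
interaction
regulate
regulates
regulated
regulation
phosphorylate
phosphorylates
phosphorylated
phosphorylation
dephosphorylate
dephosphorylates
dephosphorylated
dephosphorylation
suppress
suppresses
suppressed
suppression
repress
represses
repressed
repression
stimulate
stimulates
stimulated
stimulation
block
blocks
blocked
blockage
cleave
cleaves
cleaved
cleavage
degrade
degrades
degraded
degradation
ubiquitinate
ubiquitinates
ubiquitinated
ubiquitination
acetylate
acetylates
acetylated
acetylation
methylate
methylates
methylated
methylation
associate
associates
associated
association
promote
promotes
promoted
promotion
mediate
mediates
mediated
modulate
modulates
modulated
modulation
trigger
triggers
triggered
recruit
recruits
recruited
recruitment
stabilize
stabilizes
stabilized
stabilization
destabilize
destabilizes
destabilized
destabilization
upregulate
upregulates
upregulated
upregulation
downregulate
downregulates
downregulated
downregulation
transactivate
transactivates
transactivated
transactivation
dimerize
dimerizes
dimerized
dimerization
sequester
sequesters
sequestered
sequestration
antagonize
antagonizes
antagonized
catalyze
catalyzes
catalyzed
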