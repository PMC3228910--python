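# Tokens ending in a period that do not terminate a sentence.
# One per line; matched case-insensitively against the token preceding
# a candidate sentence boundary. Lines starting with '#' are ignored.
e.g.
i.e.
cf.
vs.
viz.
ca.
approx.
et al.
al.
Fig.
Figs.
Eq.
Eqs.
Ref.
Refs.
No.
Dr.
Prof.
St.
Mr.
Mrs.
Ms.
Inc.
Ltd.
Co.
Univ.
Dept.
sp.
spp.
subsp.
var.
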