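# Synthetic stand-in for a hypoxia metagene signature (the published
# signature's gene list is user-supplied; this file only exercises the
# median-split scoring machinery on simulated expression fixtures).
# One gene identifier per line; '#' starts a comment.
gene0
gene1
gene2
gene3
gene4
gene5
gene6
gene7
gene8
gene9
gene10
gene11
gene12
gene13
gene14
gene15
gene16
gene17
gene18
gene19
gene20
gene21
gene22
gene23
gene24
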