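# Example spare list: taxa with strong literature precedence as human
# commensals or tumor-associated organisms; sparing overrides denial.
Fusobacterium nucleatum
Bacteroides fragilis
Helicobacter pylori
Bifidobacterium
Alistipes
Malassezia
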