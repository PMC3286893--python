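# Diagnostic substitutions of the SYNTHETIC six-subfamily taxonomy used by
# the simulator (subfamily, position on the full synthetic consensus,
# derived base).  Nested: each younger subfamily carries all diagnostics of
# its ancestors plus one of its own.  Replace with real subfamily
# diagnostics when analysing genomic data.
PA3	2000	T
PA2	2000	T
PA2	2100	A
1AB	2000	T
1AB	2100	A
1AB	2200	C
preTa	2000	T
preTa	2100	A
preTa	2200	C
preTa	2300	G
Ta0	2000	T
Ta0	2100	A
Ta0	2200	C
Ta0	2300	G
Ta0	2400	T
Ta1	2000	T
Ta1	2100	A
Ta1	2200	C
Ta1	2300	G
Ta1	2400	T
Ta1	2500	A
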