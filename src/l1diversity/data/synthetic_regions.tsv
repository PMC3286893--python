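# EXAMPLE region annotations for the SYNTHETIC 5' UTR consensus (0-based
# half-open, within [0, 897)).  Window placement mimics the layout of the
# human L1 5' UTR regulatory landscape (sense promoter at the 5' end, YY1
# near +13, RUNX3 near +83, SRY-related sites mid-UTR, antisense promoter
# windows on the minus strand) but the coordinates are NOT genomic
# annotations; supply your own region file for real data.
sense-promoter	9	609	+
YY1	12	21	+
RUNX3	83	101	+
ASP	392	560	-
RUNX3-ASP	500	518	-
SRY-1	472	481	+
SRY-2	572	581	+
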