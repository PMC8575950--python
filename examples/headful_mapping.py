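"""Map loci to the headfuls that would package them, Table-4 style.

Builds a toy circular genome with two attB sites of opposite packaging
direction, places loci at known offsets, and prints which lateral-transducing
particle headful would carry each locus from each prophage.  "HF k-m" means
the locus straddles a headful boundary; "—" means it is beyond the
prophage's processive reach.
"""

from ltmob import (
    AttBSite,
    CircularInterval,
    GenomicLocus,
    ProphageModel,
    format_headful_range,
    headful_index,
    locus_compatibility_table,
)

L = 2_800_000  # a S. aureus-sized chromosome
model = ProphageModel("80alpha-like", headful_size=45_000, n_max=7)
sites = [AttBSite("Sa6", 400_000, +1), AttBSite("Sa9", 1_900_000, -1)]
models = {s.site_id: model for s in sites}

loci = [
    GenomicLocus("island_A", CircularInterval(500_000, 30_000, L)),   # ~HF3 of Sa6
    GenomicLocus("island_B", CircularInterval(620_000, 20_000, L)),   # straddles HF5/6
    GenomicLocus("marker_C", CircularInterval(1_855_000, 1_000, L)),  # HF2 of Sa9 (reverse)
    GenomicLocus("far_locus", CircularInterval(2_500_000, 5_000, L)), # out of reach
]

table = locus_compatibility_table(loci, sites, models, L)
print(f"{'locus':10s}" + "".join(f"{s.site_id:>10s}" for s in sites))
for locus in loci:
    cells = [format_headful_range(table[locus.locus_id][s.site_id]) for s in sites]
    print(f"{locus.locus_id:10s}" + "".join(f"{c:>10s}" for c in cells))

hf = headful_index(sites[0], 435_000, model, L)
print(f"\nA marker 35 kb downstream of Sa6 falls in headful {hf} (HF1:")
print("the first capsid already reaches it), matching how cadmium markers")
print("at defined headful distances are indexed from the attachment site.")
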