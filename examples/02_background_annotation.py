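"""Build a background annotation for a toy genome.

Creates one chromosome with two promoters, a CpG island and random
window GC content, then runs the filter / construct / finalize stages
and prints how many windows survive each stage. Finalized windows are
the low-GC, low-TPM regions whose counts will estimate the capture
background of each promoter.
"""

import numpy as np
import pandas as pd

from mbdcapdm import GenomeLayout, Promoter, build_background
from mbdcapdm.annotation import Window

rng = np.random.default_rng(1)
n_windows = 600
layout = GenomeLayout(
    {"chr1": n_windows * 100},
    cpg_islands={"chr1": [(20_000, 20_400)]},
    gaps={"chr1": [(45_000, 45_200)]},
)
windows = [
    Window("chr1", i * 100, (i + 1) * 100, float(rng.uniform(0.25, 0.55)))
    for i in range(n_windows)
]
promoters = [
    Promoter("GENE_A", "chr1", "+", 10_000, 8_000, 12_000),
    Promoter("GENE_B", "chr1", "-", 40_000, 38_000, 42_000),
]
window_counts = pd.DataFrame(
    {"sample1": rng.poisson(8.0, n_windows)}, index=[w.id for w in windows]
)

annotation = build_background(layout, promoters, window_counts, read_length=50,
                              windows=windows)
for p in promoters:
    cand = annotation.candidates[p.id]
    final = annotation.windows[p.id]
    print(
        f"{p.id}: {len(cand)} low-GC candidates near TSS {p.tss}, "
        f"{len(final)} finalized (closest: {final[0].id})"
    )
# Each promoter ends with <= 40 windows, all GC < 40%, outside promoters,
# the CpG island and the gap, ranked by mean TPM.
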