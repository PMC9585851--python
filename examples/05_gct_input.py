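"""Use a gene's expression row from a GCT matrix as the analyte.

GTEx-style expression matrices (GCT v1.2/1.3) can serve as a reference
population: one gene's TPMs across samples play the role of an analyte's
measurements. This example builds a small synthetic GCT in a temp file,
extracts one gene and computes its reference interval.
"""

import tempfile
from pathlib import Path

import numpy as np

from risize import nonparametric_ri, parametric_ri, tukey_filter
from risize.io import read_gct

rng = np.random.default_rng(9)
n_samples = 260
genes = {
    "NAP1L4": np.round(rng.lognormal(3.0, 0.25, n_samples), 3),
    "OTUD5": np.round(rng.lognormal(2.2, 0.40, n_samples), 3),
}
header = "Name\tDescription\t" + "\t".join(f"S{i}" for i in range(n_samples))
rows = [f"{g}\tsynthetic\t" + "\t".join(map(str, v)) for g, v in genes.items()]
gct_text = "#1.2\n" + f"{len(genes)}\t{n_samples}\n" + header + "\n" + "\n".join(rows) + "\n"

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "synthetic_expression.gct"
    path.write_text(gct_text)
    for gene in genes:
        pop = read_gct(path, gene)
        kept = tukey_filter(pop.values).kept
        p, np_ = parametric_ri(kept), nonparametric_ri(kept)
        print(f"{gene}: {pop.n} samples ({pop.unit}), "
              f"parametric RI=({p.lower:.2f}, {p.upper:.2f}), "
              f"non-parametric RI=({np_.lower:.2f}, {np_.upper:.2f})")

print("\nWith a real GTEx GCT, pass the file path and gene Name directly;")
print("the sample-size search then runs on the extracted TPM row.")
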