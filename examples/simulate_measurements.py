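"""Generate synthetic chromatid measurement tables with known ground truth.

Simulates metaphase spreads from the bundled karyotype template at two
noise levels and shows how measurement noise degrades chromosome
identification against the template.
"""

import karyomorph as km
from karyomorph.types import SimulationConfig

template = km.datasets.load_pygmaeus_template()

for cv in (0.0, 0.05, 0.10):
    cfg = SimulationConfig(
        template=template, seed=42, n_metaphases=10,
        arm_noise_cv=cv, chromatid_noise_cv=0.0,
    )
    records, truth = km.generate_metaphases(cfg)
    consensus, results, _ = km.analyze_karyotype(records, template)
    mapping = {
        (r.metaphase_id, o): t for r in results for o, t in r.mapping.items()
    }
    hits = sum(
        mapping[(r.metaphase_id, r.object_id)] == r.type_label
        for r in truth.itertuples()
    )
    n_ambiguous = sum(len(r.ambiguous) for r in results)
    print(
        f"arm noise CV {cv:4.0%}: {len(records)} chromatid rows, "
        f"2n = {consensus.two_n}, identification accuracy "
        f"{hits / len(truth):6.1%}, ambiguous objects {n_ambiguous}"
    )

print(
    "\nReading: identification is exact without noise and degrades as arm"
    "\nmeasurement error grows; morphologically similar types (e.g. 5L/5S/"
    "\n6S/7L) are the first to be confused."
)
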