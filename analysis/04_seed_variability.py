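"""Summarize subject-specific seed selection.

For every canonical seed, report how many simulated subjects had a
significant local activation peak within 18 mm (those subjects get a
subject-specific seed; the rest keep the canonical location) and the
mean peak-to-canonical distance.  Writes results/subject_seeds.tsv.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, ensure_report
from dotppi.seeds import canonical_seeds, seeds_from_tsv


def main():
    report = ensure_report()
    canon = canonical_seeds()
    subj_files = sorted(report.glob("seeds_subject_*.tsv"))
    rows = []
    for c in canon:
        dists = []
        for f in subj_files:
            s = {x.label: x for x in seeds_from_tsv(f)}[c.label]
            if s.origin == "subject_specific":
                dists.append(float(np.linalg.norm(
                    np.subtract(s.center_mm, c.center_mm))))
        rows.append({"region": c.label,
                     "n_subject_specific": len(dists),
                     "n_subjects": len(subj_files),
                     "mean_distance_mm": np.mean(dists) if dists else np.nan})
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "subject_seeds.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    n = int(table["n_subject_specific"].sum())
    print(f"\n{n} of {len(canon) * len(subj_files)} seed assignments moved to "
          f"a subject-specific peak within 18 mm; the rest kept the "
          f"canonical location.")


if __name__ == "__main__":
    main()
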