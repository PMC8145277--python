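"""Writing study reports to disk (CSV tables + JSON sidecars)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

from .io import clusters_to_json

if TYPE_CHECKING:
    from .pipeline import StudyReport


def write_report(report: "StudyReport", out_dir: str | Path) -> Path:
    """Write behavioral table, cluster results, schemes and provenance.

    Layout::

        out_dir/
          behavioral.csv      Wilcoxon/BH table (Table-1-like columns)
          eeg_clusters.json   contrast -> clusters (members, mass, p, scheme)
          eeg_schemes.csv     permutation scheme and count per contrast
          features.csv        tidy per-subject feature table
          provenance.json     config, seed, versions
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.behavioral.to_csv(out / "behavioral.csv", index=False)
    clusters_to_json(report.eeg_clusters, out / "eeg_clusters.json")
    report.eeg_schemes.to_csv(out / "eeg_schemes.csv", index=False)
    report.feature_table.to_csv(out / "features.csv", index=False)
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=1, default=str))
    return out
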