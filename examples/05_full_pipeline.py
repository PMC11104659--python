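"""Run the whole file-based pipeline end to end and inspect its artifacts.

Equivalent to `cravingminer run-all --out <dir> --seed 7` on the default
configuration; every stage writes CSV/JSONL artifacts and the manifest
records digests, so a rerun with the same seed is byte-identical.
"""

import json
from pathlib import Path
import tempfile

import pandas as pd

from cravingminer import cli

out_dir = Path(tempfile.mkdtemp()) / "run"
cfg = Path(tempfile.mkdtemp()) / "fast.cfg"
cfg.write_text("simulate.n_authors = 300\ntopics.k = 5\ntopics.iterations = 120\ntopics.burn_in = 60\n")

out = cli.run(cli.STAGE_ORDER, config_path=cfg, out_dir=out_dir, seed=7)
stats = json.loads((out / "filter_stats.json").read_text())
print(f"filter: {stats['n_craving']}/{stats['n_total']} posts retrieved "
      f"({100 * stats['retrieval_rate']:.1f}%)")

report = pd.read_csv(out / "context_report.csv")
print(f"context report covers {len(report)} categories; top rows:")
print(report.sort_values('pct_authors', ascending=False).head(4).to_string(index=False))

ev = pd.read_csv(out / "evaluation.csv")
print("\ntest-set evaluation (craving row):")
print(ev[ev["feature"] == "craving"].to_string(index=False))
print(f"\nartifacts + digests recorded in {out / 'manifest.json'}")
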