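#!/usr/bin/env python
"""Test-retest reliability of the subnetwork mean connectivity.

Builds paired retest sessions at the fair-to-good reliability regime
(target ICC 0.72) and reports ICC(2,1) / ICC(3,1) with their Fleiss
interpretation labels, at the emulated retest sample size (n = 26) and at
a large-sample check (n = 500).
"""

import json
from pathlib import Path

import numpy as np

from connlearn.stats import icc
from connlearn.synthetic import generate_retest_pair

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    payload = {}
    for n in (26, 500):
        s1, s2 = generate_retest_pair(n, icc_target=0.72, seed=1)
        res = icc(np.column_stack([s1, s2]))
        payload[f"n_{n}"] = {
            "icc_2_1": round(res.icc_2_1, 3),
            "icc_3_1": round(res.icc_3_1, 3),
            "label": res.label,
        }
        print(f"n = {n:3d}: ICC(2,1) = {res.icc_2_1:.3f}, "
              f"ICC(3,1) = {res.icc_3_1:.3f} [{res.label}]")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "reliability_icc.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
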