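#!/usr/bin/env python
"""Deadenylation kinetics on the default chase.

Position half-lives over the 40-80 A window, the apparent-to-microscopic
rate conversion, and the virtual-deadenylation (alpha) matching
cross-check.  Writes results/kinetics/kinetics_report.json.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from tailchase import workflows as wf


def _default(o: object) -> object:
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--seed", type=int, default=0, help="bootstrap seed")
    args = parser.parse_args()
    run = wf.load_run(args.results / "runs" / "mex67_chase")
    report = wf.kinetics_workflow(run, seed=args.seed)
    out = args.results / "kinetics"
    out.mkdir(parents=True, exist_ok=True)
    (out / "kinetics_report.json").write_text(
        json.dumps(report, indent=2, default=_default) + "\n"
    )
    print(json.dumps(report, indent=2, default=_default))


if __name__ == "__main__":
    main()
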