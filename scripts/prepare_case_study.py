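#!/usr/bin/env python
"""Convert an external mark-recapture table to the package's CSV dialect.

Intended for adapting deposited monitoring datasets (e.g. the night-gecko
release archive) whose wide tables carry one row per individual with
per-survey detection columns plus origin/sex metadata.  The exact column
names vary between deposits, so they are passed on the command line.

Example:
    python scripts/prepare_case_study.py raw.csv out/histories.csv \
        --id-col ID --origin-col origin --group-col sex \
        --detection-prefix occ --translocated-value released \
        --times 0,2,7,12 --tau 3 --design-out out/design.yaml
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from transjs.data import (
    CaptureData,
    CaptureHistory,
    StudyDesign,
    write_design,
    write_histories,
)


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("raw", type=Path)
    ap.add_argument("out", type=Path)
    ap.add_argument("--id-col", default="id")
    ap.add_argument("--origin-col", default="origin")
    ap.add_argument("--group-col", default=None)
    ap.add_argument("--detection-prefix", default="occ",
                    help="columns starting with this prefix are occasions, "
                    "in order of appearance")
    ap.add_argument("--translocated-value", default="translocated",
                    help="origin-column value marking released animals")
    ap.add_argument("--times", default=None,
                    help="comma list of occasion times in months")
    ap.add_argument("--tau", type=int, default=2)
    ap.add_argument("--design-out", type=Path, default=None)
    args = ap.parse_args(argv)

    df = pd.read_csv(args.raw)
    occ_cols = [c for c in df.columns if c.startswith(args.detection_prefix)]
    if not occ_cols:
        raise SystemExit(
            f"no columns start with {args.detection_prefix!r}: {list(df.columns)}"
        )
    T = len(occ_cols)
    times = (
        np.array([float(v) for v in args.times.split(",")])
        if args.times
        else np.arange(T, dtype=float)
    )
    groups = ()
    if args.group_col:
        groups = tuple(sorted(df[args.group_col].dropna().astype(str).unique()))
    design = StudyDesign(
        n_occasions=T, occasion_times=times, tau=args.tau, groups=groups
    )
    histories = []
    for _, row in df.iterrows():
        det = (row[occ_cols].astype(float) > 0).astype(np.int8).to_numpy()
        origin = (
            "translocated"
            if str(row[args.origin_col]) == args.translocated_value
            else "wild"
        )
        group = str(row[args.group_col]) if args.group_col else None
        histories.append(
            CaptureHistory(str(row[args.id_col]), origin, det, group=group)
        )
    data = CaptureData(design, histories)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_histories(data, args.out, "csv")
    if args.design_out:
        write_design(design, args.design_out)
    print(
        f"wrote {args.out}: D={data.n_observed}, n0={data.n_translocated}, "
        f"T={T}"
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
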