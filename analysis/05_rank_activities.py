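"""Rank the simulated activities under every complexity measure.

Reads the per-activity reports written by 04_activity_complexity.py and
emits the measures x activities rank table (rank 1 = most complex under
that measure) with Kendall's coefficient of concordance W. The designed
suite demonstrates the central point: different measure families crown
different activities as "most complex", while all agree the plain-walking
analog is simplest.
"""

import argparse
from pathlib import Path

from gaitcomplexity import ActivityComplexityReport, rank_activities

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reports-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    paths = sorted(args.reports_dir.glob("report_*.json"))
    if len(paths) < 2:
        raise SystemExit("need >= 2 report JSONs; run 04_activity_complexity.py first")
    reports = [ActivityComplexityReport.from_json(p.read_text()) for p in paths]
    table = rank_activities(reports)

    frame = table.to_frame()
    print(frame.to_string())
    print(f"Kendall's W across measures: {table.kendall_w:.3f}")
    winners = {
        meas: table.activities[int(table.ranks[i].argmin())]
        for i, meas in enumerate(table.measures)
    }
    print("most complex per measure:",
          ", ".join(f"{m} -> {a}" for m, a in winners.items()))

    out = args.reports_dir / "ranking.csv"
    frame.assign(kendall_w=table.kendall_w).to_csv(out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
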