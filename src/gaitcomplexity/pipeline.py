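"""Per-activity orchestration and cross-measure ranking.

``analyze_activity`` runs every measure family — stride segmentation and
101-point normalization, PCA dimensionality (N95%), generalized variance,
GaitSD, and the per-joint nonlinear chain (AMI/FNN embedding, Rosenstein
LyE, CMSE/CI) — over a set of trials with one shared configuration, and
aggregates across trials. ``rank_activities`` turns a set of activity
reports into a measures x activities rank table (rank 1 = most complex,
i.e. largest value, under each measure) and quantifies cross-measure
agreement with Kendall's coefficient of concordance W. Everything is
deterministic given inputs and configuration: serialized reports are
byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import rankdata

from .dimensionality import n95, variance_spectrum
from .kinematics import FootContactSeries, KinematicsTrial, segment_cycles, time_normalize
from .nonlinear import joint_nld_summary
from .variability import gait_sd, generalized_variance

#: measures carried into the ranking table; larger value = more complex
RANKED_MEASURES = ("n95", "log_gv", "gait_sd", "lye", "ci")


@dataclass
class AnalysisConfig:
    n95_threshold: float = 0.95
    phase_points: int = 101
    min_cycle_duration_s: float = 0.4
    gait_sd_combiner: str = "mean_of_sd"
    nld_max_dim: int = 8
    nld_n_scales: int = 20
    nld_m: int = 2
    nld_r_factor: float = 0.2
    nld_min_samples: int = 500


@dataclass
class ActivityComplexityReport:
    activity_label: str
    per_trial: list[dict]
    aggregate: dict  # measure -> {"mean":, "sd":, "n":}
    n_trials: int
    n_cycles: int
    config: dict
    warnings: list[str] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, text: str) -> "ActivityComplexityReport":
        return cls(**json.loads(text))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _aggregate(values: list[float]) -> dict:
    arr = np.asarray(
        [v for v in values if v is not None and np.isfinite(v)], dtype=float
    )
    if arr.size == 0:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd, "n": int(arr.size)}


def analyze_trial(
    trial: KinematicsTrial,
    contacts: FootContactSeries,
    config: AnalysisConfig,
) -> tuple[dict, list[str]]:
    """All measure families for one trial; returns (record, warnings)."""
    warnings_: list[str] = []
    record: dict = {"trial_id": trial.trial_id}

    spectrum = variance_spectrum(trial.samples)
    record["n95"] = n95(spectrum, config.n95_threshold)
    record["eigenvalues"] = spectrum.eigenvalues.tolist()

    gv = generalized_variance(trial.samples)
    record["gv"] = gv.gv
    record["log_gv"] = gv.log_gv if np.isfinite(gv.log_gv) else None
    record["normalized_gv"] = gv.normalized_gv
    record["rank_deficient"] = gv.rank_deficient
    if gv.rank_deficient:
        warnings_.append(f"{trial.trial_id}: covariance rank deficient, GV = 0")

    cycles = time_normalize(
        segment_cycles(trial, contacts, config.min_cycle_duration_s),
        n_points=config.phase_points,
        channels=trial.channels,
        source_trial_ids=(trial.trial_id,),
    )
    record["n_cycles"] = cycles.n_cycles
    gsd = gait_sd(cycles, combiner=config.gait_sd_combiner)
    record["gait_sd"] = gsd.gait_sd

    nld = joint_nld_summary(
        trial,
        max_dim=config.nld_max_dim,
        n_scales=config.nld_n_scales,
        m=config.nld_m,
        r_factor=config.nld_r_factor,
        min_samples=config.nld_min_samples,
    )
    record["per_joint"] = {}
    for ch, res in nld.items():
        record["per_joint"][ch] = {
            "delay": res.embedding.delay,
            "dim": res.embedding.dim,
            "ami_fallback": res.ami.fallback_used,
            "fnn_saturated": res.fnn.saturated,
            "lye": res.lye.lye,
            "ci": res.cmse.ci,
            "ci_defined": res.cmse.ci_defined,
        }
        warnings_.extend(res.warnings)
    lyes = [v["lye"] for v in record["per_joint"].values()]
    cis = [v["ci"] for v in record["per_joint"].values() if v["ci_defined"]]
    record["lye"] = float(np.mean(lyes)) if lyes else float("nan")
    record["ci"] = float(np.mean(cis)) if cis else float("nan")
    return record, warnings_


def analyze_activity(
    trials: list[KinematicsTrial],
    contacts: list[FootContactSeries],
    config: AnalysisConfig | None = None,
    activity_label: str | None = None,
) -> ActivityComplexityReport:
    """Run every measure family over an activity's trials and aggregate.

    A trial whose analysis raises a structured error is recorded under
    ``failures`` (with its id and message) and the remaining trials are
    still processed.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if len(trials) != len(contacts):
        raise ValueError("trials and contacts must pair up")
    config = config or AnalysisConfig()
    label = activity_label or trials[0].activity_label
    per_trial, warnings_, failures = [], [], []
    for trial, cont in zip(trials, contacts):
        try:
            rec, warns = analyze_trial(trial, cont, config)
        except (ValueError, KeyError) as exc:
            failures.append({"trial_id": trial.trial_id, "error": str(exc)})
            continue
        per_trial.append(rec)
        warnings_.extend(warns)

    aggregate = {
        meas: _aggregate([rec[meas] for rec in per_trial])
        for meas in ("n95", "log_gv", "normalized_gv", "gait_sd", "lye", "ci")
    }
    return ActivityComplexityReport(
        activity_label=label,
        per_trial=per_trial,
        aggregate=aggregate,
        n_trials=len(per_trial),
        n_cycles=int(sum(rec["n_cycles"] for rec in per_trial)),
        config=asdict(config),
        warnings=warnings_,
        failures=failures,
    )


# ----------------------------------------------------------------- ranking


@dataclass
class RankingTable:
    measures: tuple[str, ...]
    activities: tuple[str, ...]
    ranks: np.ndarray  # measures x activities; 1 = most complex, ties -> mean rank
    values: np.ndarray  # the aggregate means being ranked
    kendall_w: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.ranks, index=list(self.measures),
                            columns=list(self.activities))


def kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance for an m x n rank matrix.

    Rows are judges (measures), columns objects (activities); ties must
    already carry mean ranks. Tie-corrected:

        W = (12 S) / (m^2 (n^3 - n) - m sum_i T_i),  S = sum_j (R_j - R̄)^2

    with T_i = sum over tie groups of (t^3 - t) in row i.
    """
    ranks = np.asarray(ranks, dtype=float)
    m, n = ranks.shape
    if n < 2:
        raise ValueError("need at least 2 objects to rank")
    col_sums = ranks.sum(axis=0)
    s = float(((col_sums - col_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:  # every row fully tied
        return 0.0
    return 12.0 * s / denom


def rank_activities(
    reports: list[ActivityComplexityReport],
    measures: tuple[str, ...] = RANKED_MEASURES,
) -> RankingTable:
    """Rank activities under each measure (1 = largest = most complex)."""
    if len(reports) < 2:
        raise ValueError("need >= 2 activity reports to rank")
    activities = tuple(r.activity_label for r in reports)
    values = np.empty((len(measures), len(reports)))
    for i, meas in enumerate(measures):
        for j, rep in enumerate(reports):
            if meas not in rep.aggregate or rep.aggregate[meas]["n"] == 0:
                raise ValueError(
                    f"measure {meas!r} missing from activity {rep.activity_label!r}"
                )
            values[i, j] = rep.aggregate[meas]["mean"]
    # rankdata ranks ascending; negate so the largest value gets rank 1
    ranks = np.vstack([rankdata(-row, method="average") for row in values])
    return RankingTable(
        measures=tuple(measures),
        activities=activities,
        ranks=ranks,
        values=values,
        kendall_w=kendall_w(ranks),
    )
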