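"""Evaluation of screening rankings against simulation ground truth.

Two metrics: the area under the precision–recall curve, computed with the
average-precision estimator (step-wise, no linear interpolation, tied
scores collapsed into one group), and the Spearman rank correlation
between true absolute coefficients and absolute scores. ``run_study``
replicates scenarios from a grid configuration and tabulates both metrics
per method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cox import cox_scores
from .scoring import cars_scores
from .simulate import SimulationDesign, replicate_design, scenario_calibration, simulate_dataset

__all__ = ["precision_recall_auc", "rank_correlation", "run_study", "summarize_study"]


def precision_recall_auc(abs_scores, truth) -> float:
    """Average-precision PR-AUC of a ranking against binary truth labels.

    Thresholds sweep the distinct score values in descending order; each
    group of tied scores enters as one block and every positive in the
    block receives the block-level precision. With all scores equal the
    curve degenerates to a single point and the value is the prevalence
    (the random-classifier baseline).
    """
    s = np.asarray(abs_scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length vectors")
    n_pos = int(t.sum())
    if n_pos == 0:
        raise ValueError("no positive labels: PR-AUC undefined")

    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    # group boundaries: last index of each distinct score value
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    group_ends = np.concatenate([boundary, [s.size - 1]])
    tp_cum = np.cumsum(t_sorted)[group_ends]
    k_cum = group_ends + 1
    precision = tp_cum / k_cum
    pos_in_group = np.diff(np.concatenate([[0], tp_cum]))
    return float(np.sum(precision * pos_in_group) / n_pos)


def rank_correlation(true_abs_beta, abs_scores) -> float:
    """Spearman correlation (average-rank ties) of true vs estimated |effects|."""
    a = np.asarray(true_abs_beta, dtype=float)
    b = np.asarray(abs_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined: a vector has zero variance")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def _scenario_design(spec: dict, seed: int) -> SimulationDesign:
    fields = {
        k: spec[k]
        for k in (
            "n",
            "d",
            "rel_var",
            "block_rhos",
            "signal_block",
            "family",
            "exp_var",
            "snr",
            "cens_rate",
            "admin_quantile",
            "cens_log_sd",
            "pilot_size",
        )
        if k in spec
    }
    if "block_rhos" in fields:
        fields["block_rhos"] = tuple(fields["block_rhos"])
    return SimulationDesign(seed=seed, **fields)


def run_study(grid: dict) -> pd.DataFrame:
    """Run a replicated scenario study and return a tidy results table.

    ``grid`` is a mapping with keys ``base_seed`` (int), ``replications``
    (int, may be overridden per scenario) and ``scenarios`` — a list of
    mappings with :class:`~carscreen.simulate.SimulationDesign` fields.
    Per-replicate seeds derive deterministically from the base seed, so the
    whole table is reproducible. Each replicate contributes one row per
    method ("cars", "cox") with both metrics.
    """
    base_seed = int(grid.get("base_seed", 0))
    default_reps = int(grid.get("replications", 1))
    scenarios = grid["scenarios"]
    rows = []
    for s_idx, spec in enumerate(scenarios):
        reps = int(spec.get("replications", default_reps))
        scen_seed = (base_seed + 7919 * (s_idx + 1)) % (2**31 - 1)
        design = _scenario_design(spec, scen_seed)
        cal = scenario_calibration(design)
        truth = cal.influential
        true_abs = np.abs(cal.beta)
        for rep in range(reps):
            rep_seed = (scen_seed + 104729 * (rep + 1)) % (2**31 - 1)
            ds = simulate_dataset(replicate_design(design, rep_seed), cal)
            try:
                scored = {
                    "cars": np.abs(cars_scores(ds.sample).scores),
                    "cox": np.abs(cox_scores(ds.sample).z_scores),
                }
            except ValueError as e:
                raise RuntimeError(
                    f"scenario {s_idx} replicate {rep} (seed {rep_seed}) failed: {e}"
                ) from e
            for method, abs_s in scored.items():
                rows.append(
                    {
                        "scenario": s_idx,
                        "method": method,
                        "replicate": rep,
                        "seed": rep_seed,
                        "n": design.n,
                        "d": design.d,
                        "rel_var": design.rel_var,
                        "family": design.family,
                        "exp_var": design.exp_var,
                        "snr": design.snr,
                        "cens_rate": design.cens_rate,
                        "signal_block": design.signal_block,
                        "pr_auc": precision_recall_auc(abs_s, truth),
                        "rank_corr": rank_correlation(true_abs, abs_s),
                        "realized_cens_rate": ds.realized_cens_rate,
                    }
                )
    return pd.DataFrame(rows)


def summarize_study(records: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario, per-method medians and IQRs of both metrics."""

    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return q3 - q1

    return (
        records.groupby(["scenario", "method"])
        .agg(
            pr_auc_median=("pr_auc", "median"),
            pr_auc_iqr=("pr_auc", iqr),
            rank_corr_median=("rank_corr", "median"),
            rank_corr_iqr=("rank_corr", iqr),
            n_replicates=("replicate", "count"),
        )
        .reset_index()
    )
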