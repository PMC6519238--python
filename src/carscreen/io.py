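"""Delimited-text input/output for survival tables and score reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sample import SurvivalSample

_FLOAT_FMT = "%.12g"


def read_survival_table(
    path,
    time_col: str = "time",
    status_col: str = "status",
    transpose: bool = False,
) -> SurvivalSample:
    """Read a delimited survival table into a validated sample.

    The file must be TSV or CSV (autodetected by extension) with a header;
    the ``time`` and ``status`` columns are required and every remaining
    column is treated as a covariate. Rows containing missing values are
    rejected with a count. ``transpose`` pivots a covariates-in-rows matrix
    (common for omics exports) before looking for the outcome columns.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(drop=True)
        df.columns.name = None
        df = df.apply(pd.to_numeric)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"required column '{col}' not found in {path.name}")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        raise ValueError(
            f"{n_missing} row(s) contain missing values; the estimators assume "
            "complete data (impute upstream)"
        )
    times = df[time_col].to_numpy(dtype=float)
    status = df[status_col].to_numpy()
    bad_status = ~np.isin(status, [0, 1])
    if bad_status.any():
        rows = np.flatnonzero(bad_status)[:5].tolist()
        raise ValueError(f"status must be 0/1; offending row index(es) {rows}")
    bad_time = ~(times > 0)
    if bad_time.any():
        rows = np.flatnonzero(bad_time)[:5].tolist()
        raise ValueError(
            f"times must be strictly positive (log undefined); row index(es) {rows}"
        )
    covs = df.drop(columns=[time_col, status_col])
    return SurvivalSample(
        times, status.astype(np.int8), covs.to_numpy(dtype=float), tuple(covs.columns)
    )


def score_table(result, selection=None) -> pd.DataFrame:
    """Assemble the ranked-score table shared by the CARS and Cox screens.

    ``result`` is a :class:`~carscreen.scoring.CARSResult` or a
    ``(scores, names)``-like object; ``selection`` optionally adds q-value
    and selected columns from a mixture fit paired with an ``alpha1``.
    """
    from .scoring import CARSResult, abs_ranks

    if isinstance(result, CARSResult):
        df = pd.DataFrame(
            {
                "covariate": list(result.covariate_names),
                "score": result.scores,
                "abs_rank": result.abs_rank,
                "marginal_corr": result.marginal_corr,
            }
        )
    else:  # Cox score vector + names
        scores, names = result
        scores = np.asarray(scores, dtype=float)
        df = pd.DataFrame(
            {
                "covariate": list(names),
                "score": scores,
                "abs_rank": abs_ranks(scores),
            }
        )
    if selection is not None:
        fit, alpha1 = selection
        df["q_value"] = fit.q_values
        df["selected"] = fit.q_values < alpha1
    return df


def write_score_table(df: pd.DataFrame, path) -> None:
    """Write a score table as TSV with stable float formatting.

    Round-tripping through :func:`read_score_table` restores values to
    1e−12; identical inputs give byte-identical files.
    """
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
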