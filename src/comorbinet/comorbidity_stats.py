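"""Clinical co-occurrence statistics and their correlation with network scores.

From patient diagnosis records, each unordered disease pair (i, j) gets a
contingency summary: C_ij patients diagnosed with both, I_i and I_j patients
with each disease, N total patients. Derived measures:

* relative risk  RR = RP_ij / IP_ij = (C_ij/N) / ((I_i/N)(I_j/N)),
  equal to 1 under independence;
* phi correlation  PHI = (C_ij*N - I_i*I_j) / sqrt(I_i*I_j*(N-I_i)*(N-I_j)),
  the Pearson correlation of the two binary disease indicators.

Significance of a Pearson correlation between molecular scores (XD, NG) and
clinical scores (RR, PHI) is estimated by Monte-Carlo permutation: one list
is shuffled n_perm times and the p-value is the fraction of permuted
coefficients strictly larger than the observed one (one-sided, no add-one
smoothing; the minimum resolvable p is 1/n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network_io import PatientRecords
from .xd_scoring import (
    CATEGORY_BOTH,
    CATEGORY_NEITHER,
    CATEGORY_NG_ONLY,
    CATEGORY_XD_ONLY,
)

__all__ = [
    "CooccurrenceCounts",
    "CorrelationReport",
    "UndefinedStatisticError",
    "cooccurrence",
    "relative_risk",
    "phi_correlation",
    "pearson",
    "permutation_pvalue",
    "category_correlations",
    "category_summaries",
    "PAIR_FILTERS",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given counts."""


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Contingency counts for one unordered disease pair."""

    disease_i: str
    disease_j: str
    c_ij: int
    i_i: int
    i_j: int
    n: int

    def __post_init__(self):
        if not (0 <= self.c_ij <= min(self.i_i, self.i_j) <= self.n):
            raise ValueError(f"inconsistent counts: {self}")

    @property
    def rp(self) -> float:
        """Observed co-occurrence probability C_ij / N."""
        return self.c_ij / self.n

    @property
    def ip(self) -> float:
        """Joint probability under independence (I_i/N)(I_j/N)."""
        return (self.i_i / self.n) * (self.i_j / self.n)


def relative_risk(c: CooccurrenceCounts) -> float:
    """RR = RP/IP = C_ij * N / (I_i * I_j); undefined when a disease is absent."""
    if c.i_i == 0 or c.i_j == 0:
        raise UndefinedStatisticError(
            f"RR undefined for ({c.disease_i}, {c.disease_j}): a marginal count is 0"
        )
    return c.c_ij * c.n / (c.i_i * c.i_j)


def phi_correlation(c: CooccurrenceCounts) -> float:
    """Pearson correlation of the two binary disease indicators.

    Undefined when either disease is carried by no patient or by every
    patient (zero variance in the indicator).
    """
    if not (0 < c.i_i < c.n and 0 < c.i_j < c.n):
        raise UndefinedStatisticError(
            f"PHI undefined for ({c.disease_i}, {c.disease_j}): "
            "a disease is present in all or no patients"
        )
    num = c.c_ij * c.n - c.i_i * c.i_j
    den = math.sqrt(c.i_i * c.i_j * (c.n - c.i_i) * (c.n - c.i_j))
    return num / den


def cooccurrence(
    records: PatientRecords, diseases: Iterable[str] | None = None
) -> pd.DataFrame:
    """Contingency counts and RR/PHI for every unordered disease pair.

    Diseases default to all diseases observed in the records (so every pair
    has I_i, I_j >= 1); an explicit disease set may include unobserved
    diseases, whose pairs carry NaN statistics. Columns: disease_i,
    disease_j, c_ij, i_i, i_j, n, rr, phi (NaN where undefined).
    """
    if records.n_patients < 1:
        raise ValueError("patient records are empty")
    if diseases is None:
        disease_list = list(records.diseases)
    else:
        disease_list = sorted(set(diseases))
    if len(disease_list) < 2:
        raise ValueError("need at least two diseases")
    didx = {d: k for k, d in enumerate(disease_list)}
    n_pat = records.n_patients
    rows_i, rows_j = [], []
    for p_row, (_, diag) in enumerate(sorted(records.diagnoses.items())):
        for d in diag:
            if d in didx:
                rows_i.append(p_row)
                rows_j.append(didx[d])
    nd = len(disease_list)
    b = sp.csr_array(
        (np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n_pat, nd)
    )
    joint = (b.T @ b).toarray().astype(np.int64)
    marginals = np.diag(joint)
    out = []
    for a in range(nd):
        for bix in range(a + 1, nd):
            c_ij = int(joint[a, bix])
            i_i, i_j = int(marginals[a]), int(marginals[bix])
            rr = c_ij * n_pat / (i_i * i_j) if i_i and i_j else np.nan
            if 0 < i_i < n_pat and 0 < i_j < n_pat:
                phi = (c_ij * n_pat - i_i * i_j) / math.sqrt(
                    i_i * i_j * (n_pat - i_i) * (n_pat - i_j)
                )
            else:
                phi = np.nan
            out.append(
                dict(
                    disease_i=disease_list[a], disease_j=disease_list[bix],
                    c_ij=c_ij, i_i=i_i, i_j=i_j, n=n_pat, rr=rr, phi=phi,
                )
            )
    return pd.DataFrame(
        out, columns=["disease_i", "disease_j", "c_ij", "i_i", "i_j", "n", "rr", "phi"]
    )


# ---------------------------------------------------------------------------
# correlation machinery


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient; errors on n < 3 or zero variance."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(xa) < 3:
        raise UndefinedStatisticError("need at least 3 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise UndefinedStatisticError("zero variance in one of the variables")
    return float(np.dot(xc, yc) / (nx * ny))


@dataclass
class CorrelationReport:
    """One observed PCC with its Monte-Carlo permutation p-value."""

    x_label: str
    y_label: str
    pcc: float
    n_pairs: int
    n_permutations: int
    p_value: float
    seed: int | None
    min_p: float  # 1 / n_permutations, the smallest resolvable p


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 2_000_000,
    seed: int | None = None,
    labels: tuple[str, str] = ("x", "y"),
    chunk_size: int = 8192,
) -> CorrelationReport:
    """One-sided permutation p for the Pearson correlation of x and y.

    y is independently reshuffled ``n_perm`` times (seeded generator) and the
    p-value is the fraction of permuted coefficients strictly greater than
    the observed one. Shuffling only one list is equivalent in distribution
    to shuffling both. Bit-reproducible for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = pearson(x, y)
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        k = min(chunk_size, n_perm - done)
        block = np.tile(yc, (k, 1))
        rng.permuted(block, axis=1, out=block)
        r = (block @ xc) / denom
        exceed += int((r > obs).sum())
        done += k
    return CorrelationReport(
        x_label=labels[0], y_label=labels[1], pcc=obs, n_pairs=len(xa),
        n_permutations=n_perm, p_value=exceed / n_perm, seed=seed,
        min_p=1.0 / n_perm,
    )


def _filter_masks(df: pd.DataFrame) -> dict[str, pd.Series]:
    scor = df["scorable"].astype(bool)
    pos_xd = scor & (df["xd"] > 0)
    pos_ng = df["ng"] >= 1
    return {
        CATEGORY_BOTH: pos_xd & pos_ng,
        "+XD": pos_xd,
        "+NG": scor & pos_ng,
        CATEGORY_NG_ONLY: scor & pos_ng & ~pos_xd,
        CATEGORY_XD_ONLY: pos_xd & ~pos_ng,
        CATEGORY_NEITHER: scor & ~pos_xd & ~pos_ng,
        "ALL": scor,
    }


def _join_pairs(pairs: pd.DataFrame, cooc: pd.DataFrame) -> pd.DataFrame:
    return pairs.merge(
        cooc,
        left_on=["disease_a", "disease_b"],
        right_on=["disease_i", "disease_j"],
        how="inner",
    )


def category_correlations(
    pairs: pd.DataFrame,
    cooc: pd.DataFrame,
    n_perm: int = 2_000_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """PCC + permutation p for each pair filter x score pairing.

    Filters: the four exclusive categories, the two marginal filters (+XD,
    +NG), and ALL scorable pairs. Score pairings: XD and NG each against RR
    and PHI. Cells where a variable is constant within the filter (e.g. NG
    inside +XDnot+NG is identically zero) or where fewer than three pairs
    survive are emitted as NA with a reason, mirroring the NA cells of a
    per-category correlation table. Pairs with undefined RR/PHI are dropped
    per cell, with the retained count reported.
    """
    merged = _join_pairs(pairs, cooc)
    masks = _filter_masks(merged)
    cells = [
        (fname, xvar, yvar)
        for fname in masks
        for xvar in ("xd", "ng")
        for yvar in ("rr", "phi")
    ]
    children = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for (fname, xvar, yvar), child in zip(cells, children):
        sub = merged[masks[fname]][[xvar, yvar]].dropna()
        note = ""
        pcc = p_val = np.nan
        n_used = len(sub)
        if n_used < 3:
            note = "fewer than 3 pairs"
        else:
            try:
                report = permutation_pvalue(
                    sub[xvar].to_numpy(), sub[yvar].to_numpy(),
                    n_perm=n_perm,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    labels=(xvar, yvar),
                )
                pcc, p_val = report.pcc, report.p_value
            except UndefinedStatisticError:
                note = "constant variable"
        rows.append(
            dict(
                filter=fname, x_var=xvar.upper(), y_var=yvar.upper(),
                n_pairs=n_used, pcc=pcc, p_value=p_val,
                n_permutations=n_perm, note=note,
            )
        )
    return pd.DataFrame(rows)


def category_summaries(pairs: pd.DataFrame, cooc: pd.DataFrame) -> pd.DataFrame:
    """Pair counts plus mean and standard error of RR and PHI per filter."""
    merged = _join_pairs(pairs, cooc)
    rows = []
    for fname, mask in _filter_masks(merged).items():
        sub = merged[mask]
        row: dict = {"filter": fname, "n_pairs": len(sub)}
        for var in ("rr", "phi"):
            vals = sub[var].dropna().to_numpy()
            row[f"mean_{var}"] = vals.mean() if len(vals) else np.nan
            row[f"se_{var}"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) >= 2 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["filter", "n_pairs", "mean_rr", "se_rr", "mean_phi", "se_phi"]
    )


PAIR_FILTERS = (
    CATEGORY_BOTH, "+XD", "+NG", CATEGORY_NG_ONLY, CATEGORY_XD_ONLY,
    CATEGORY_NEITHER, "ALL",
)
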