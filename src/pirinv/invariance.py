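"""Concentration-invariance statistics for single cells and populations.

Each cell's 36 responses (3 odorants x 3 concentrations x 4 trials) are fit
with a fixed-effects linear model containing odorant identity,
concentration, their interaction, and trial number, using type II sums of
squares (each factor's SS is the residual-SS drop when it is added to the
model containing all other terms, respecting marginality for the
interaction).  A cell is concentration-invariant iff identity is significant
(p < alpha) while concentration and the identity x concentration interaction
are not (p > alpha).  Because the intersection multiplies the false-positive
rates of the three tests, the FPR of the invariant call on null data is
bounded by alpha.

Population-level overrepresentation is tested with a cell-identity shuffle
bootstrap: cell indices are permuted independently within each of the nine
odorant-concentration blocks (the four trials of a cell-odor-concentration
triplet stay together), which preserves every block's marginal response
distribution while destroying cross-stimulus structure within cells.

Every design matrix is shared by all cells, so ANOVAs are computed for whole
populations at once via cached projection matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core import ResponseTable

CATEGORIES = ("concentration_invariant", "identity_and_concentration",
              "mixed_interaction", "concentration_only", "unmodulated",
              "degenerate")


@dataclass
class AnovaResult:
    """Per-cell three-test outcome."""

    p_identity: float
    p_concentration: float
    p_interaction: float
    p_trial: float
    category: str


@dataclass
class BootstrapResult:
    """Identity-shuffle bootstrap of the invariant-cell fraction."""

    observed_fraction: float              # % of cells
    null_fractions: np.ndarray            # % per replicate
    p: float
    n_cells: int


# --------------------------------------------------------------------------
# vectorized type II ANOVA
# --------------------------------------------------------------------------

def _dummies(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment (reference level 0) coding, (n_obs, n_levels - 1)."""
    return (levels[:, None] == np.arange(1, n_levels)[None, :]).astype(float)


@lru_cache(maxsize=8)
def _design(n_odor: int, n_conc: int, n_trial: int) -> dict:
    """Residual-projection matrices for the full and each reduced model."""
    o, c, t = np.meshgrid(np.arange(n_odor), np.arange(n_conc),
                          np.arange(n_trial), indexing="ij")
    o, c, t = o.ravel(), c.ravel(), t.ravel()
    n_obs = o.size
    one = np.ones((n_obs, 1))
    do = _dummies(o, n_odor)
    dc = _dummies(c, n_conc)
    dt = _dummies(t, n_trial)
    doc = np.einsum("ij,ik->ijk", do, dc).reshape(n_obs, -1)

    def resid_proj(*blocks: np.ndarray) -> np.ndarray:
        x = np.hstack((one,) + blocks)
        return np.eye(n_obs) - x @ np.linalg.pinv(x)

    models = {
        "full": resid_proj(do, dc, doc, dt),
        "no_identity": resid_proj(dc, dt),
        "with_identity": resid_proj(do, dc, dt),
        "no_concentration": resid_proj(do, dt),
        "no_interaction": resid_proj(do, dc, dt),
        "no_trial": resid_proj(do, dc, doc),
    }
    df = {
        "identity": n_odor - 1,
        "concentration": n_conc - 1,
        "interaction": (n_odor - 1) * (n_conc - 1),
        "trial": n_trial - 1,
        "resid": n_obs - (1 + (n_odor - 1) + (n_conc - 1)
                          + (n_odor - 1) * (n_conc - 1) + (n_trial - 1)),
    }
    return {"models": models, "df": df, "n_obs": n_obs}


def anova_population(responses: np.ndarray, alpha: float = 0.01
                     ) -> pd.DataFrame:
    """Type II three-way fixed-effects ANOVA for every cell at once.

    ``responses`` has shape (n_cells, n_odorants, n_concentrations,
    n_trials); the observation order within a cell matches that layout.
    Returns a frame with the four p-values and the assigned category per
    cell.  Cells with zero residual variance get NaN p-values and category
    'degenerate'.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 4:
        raise ValueError("responses must be (cells, odorants, concs, trials)")
    n_cells = responses.shape[0]
    d = _design(*responses.shape[1:])
    y = responses.reshape(n_cells, -1).T            # n_obs x n_cells

    def rss(name: str) -> np.ndarray:
        r = d["models"][name] @ y
        return (r * r).sum(axis=0)

    rss_full = rss("full")
    df = d["df"]
    scale = np.max(np.abs(y), axis=0) ** 2 + 1.0
    ok = rss_full > 1e-12 * scale * d["n_obs"]

    def p_for(factor: str, reduced: str, with_model: str) -> np.ndarray:
        ss = np.maximum(rss(reduced) - rss(with_model), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df[factor]) / (rss_full / df["resid"])
        p = stats.f.sf(f, df[factor], df["resid"])
        return np.where(ok, p, np.nan)

    p_id = p_for("identity", "no_identity", "with_identity")
    p_conc = p_for("concentration", "no_concentration", "with_identity")
    p_inter = p_for("interaction", "no_interaction", "full")
    p_trial = p_for("trial", "no_trial", "full")

    category = np.full(n_cells, "unmodulated", dtype=object)
    category[p_inter < alpha] = "mixed_interaction"
    inv = (p_id < alpha) & ~(p_conc < alpha) & ~(p_inter < alpha)
    both = (p_id < alpha) & (p_conc < alpha) & ~(p_inter < alpha)
    conc_only = ~(p_id < alpha) & (p_conc < alpha) & ~(p_inter < alpha)
    category[both] = "identity_and_concentration"
    category[conc_only] = "concentration_only"
    category[inv] = "concentration_invariant"
    category[~ok] = "degenerate"
    return pd.DataFrame({
        "p_identity": p_id, "p_concentration": p_conc,
        "p_interaction": p_inter, "p_trial": p_trial,
        "category": category,
    })


def anova_cell(responses: np.ndarray, alpha: float = 0.01) -> AnovaResult:
    """Three-test classification of a single cell (odor x conc x trial)."""
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 3:
        raise ValueError("cell responses must be (odorants, concs, trials)")
    row = anova_population(responses[None], alpha).iloc[0]
    return AnovaResult(p_identity=float(row.p_identity),
                       p_concentration=float(row.p_concentration),
                       p_interaction=float(row.p_interaction),
                       p_trial=float(row.p_trial),
                       category=str(row.category))


# --------------------------------------------------------------------------
# population-level machinery
# --------------------------------------------------------------------------

def _responses_by_factor(table: ResponseTable) -> np.ndarray:
    """(n_cells, n_odorants, n_concs, n_trials) from a response table."""
    arr = table.array()
    stimuli = table.stimuli
    odorants = sorted({o for o, _ in stimuli})
    dilutions = sorted({d for _, d in stimuli})
    if len(stimuli) != len(odorants) * len(dilutions):
        raise ValueError("stimulus set is not a full odorant x dilution grid")
    # table.stimuli is sorted (odorant, dilution), i.e. odorant-major
    return arr.reshape(arr.shape[0], len(odorants), len(dilutions),
                       arr.shape[2])


def classify_population(table: ResponseTable, alpha: float = 0.01,
                        procedure: str = "single") -> dict:
    """Per-cell categories and population fractions.

    ``procedure='single'`` runs one ANOVA with three tests per cell;
    ``'successive'`` first removes interaction-significant cells, then
    applies the identity and concentration tests to the remainder — the
    concentration-invariant set is identical by construction.  Degenerate
    (zero-residual-variance) cells are excluded from fraction denominators.
    """
    if procedure not in ("single", "successive"):
        raise ValueError("procedure must be 'single' or 'successive'")
    responses = _responses_by_factor(table)
    cells = anova_population(responses, alpha)
    cells.insert(0, "cell_id", table.cell_ids)
    valid = cells["category"] != "degenerate"
    n_valid = int(valid.sum())
    fractions = {
        cat: 100.0 * float((cells.loc[valid, "category"] == cat).mean())
        if n_valid else float("nan") for cat in CATEGORIES[:-1]}
    identity_sig = valid & (cells["p_identity"] < alpha)
    inv = cells["category"] == "concentration_invariant"
    return {
        "cells": cells,
        "fractions_pct": fractions,
        "invariant_pct": fractions["concentration_invariant"],
        "invariant_pct_of_identity_sig":
            100.0 * float(inv[identity_sig].mean())
            if identity_sig.any() else float("nan"),
        "n_valid": n_valid,
        "n_degenerate": int((~valid).sum()),
    }


def _invariant_fraction(responses: np.ndarray, alpha: float) -> float:
    cells = anova_population(responses, alpha)
    valid = cells["category"] != "degenerate"
    if not valid.any():
        return float("nan")
    return 100.0 * float(
        (cells.loc[valid, "category"] == "concentration_invariant").mean())


def bootstrap_identity_shuffle(table: ResponseTable, n_boot: int = 1000,
                               seed: int | None = None,
                               alpha: float = 0.01) -> BootstrapResult:
    """Cell-identity shuffle null for the invariant-cell fraction.

    Each replicate independently permutes the cell axis within every
    odorant-concentration block, keeping the four trials of a triplet
    together, then reruns the full three-test classification.  The p-value
    is the add-one fraction of replicates whose invariant fraction reaches
    the observed one.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    responses = _responses_by_factor(table)
    n_cells, n_odor, n_conc, n_trials = responses.shape
    observed = _invariant_fraction(responses, alpha)
    flat = responses.reshape(n_cells, n_odor * n_conc, n_trials)
    null = np.empty(n_boot)
    for b in range(n_boot):
        shuffled = np.empty_like(flat)
        for s in range(flat.shape[1]):
            shuffled[:, s, :] = flat[rng.permutation(n_cells), s, :]
        null[b] = _invariant_fraction(
            shuffled.reshape(responses.shape), alpha)
    p = (float((null >= observed).sum()) + 1.0) / (n_boot + 1.0)
    return BootstrapResult(observed_fraction=observed, null_fractions=null,
                           p=p, n_cells=n_cells)


def per_site_significance(sites: list[ResponseTable], n_boot: int = 1000,
                          seed: int | None = None, alpha: float = 0.01
                          ) -> pd.DataFrame:
    """Flag sites whose invariant count beats the 99th null percentile."""
    rng = np.random.default_rng(seed)
    rows = []
    for k, site in enumerate(sites):
        boot = bootstrap_identity_shuffle(
            site, n_boot=n_boot, seed=int(rng.integers(2 ** 31)),
            alpha=alpha)
        crit = float(np.quantile(boot.null_fractions, 0.99))
        rows.append({"site": k, "observed_pct": boot.observed_fraction,
                     "null_q99_pct": crit,
                     "significant": boot.observed_fraction > crit,
                     "p": boot.p})
    return pd.DataFrame(rows)


def subsample_comparison(table: ResponseTable, n_target: int,
                         n_iter: int = 1000, seed: int | None = None,
                         alpha: float = 0.01) -> np.ndarray:
    """Invariant fractions over random cell subsamples (no replacement).

    Because the per-cell ANOVA is independent across cells, the full-table
    classification is computed once and subsampling draws from the per-cell
    flags.
    """
    responses = _responses_by_factor(table)
    if n_target > responses.shape[0]:
        raise ValueError("n_target exceeds the number of cells")
    cells = anova_population(responses, alpha)
    valid = (cells["category"] != "degenerate").to_numpy()
    inv = (cells["category"] == "concentration_invariant").to_numpy()
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    n = responses.shape[0]
    for i in range(n_iter):
        pick = rng.choice(n, size=n_target, replace=False)
        v = valid[pick]
        out[i] = 100.0 * inv[pick][v].mean() if v.any() else np.nan
    return out
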