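"""Population-vector statistics: correlations, sparseness, PCA, tuning.

A population vector is one trial's vector of per-cell responses, each the
mean deconvolved dF/F over the 4 s following odor onset.  From the resulting
cells x trials matrix this module computes trial-by-trial Pearson
correlation matrices and their within/between-stimulus summaries, lifetime
sparseness per cell, activated/suppressed fractions, preferred odorants, PCA
projections and a hierarchical-clustering row ordering for display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .core import ResponseTable, TrialTensor


def build_population_vectors(tensor: TrialTensor, window_s: float = 4.0
                             ) -> ResponseTable:
    """Mean deconvolved signal over the post-onset window, per trial."""
    onset = tensor.onset_frame
    n_win = int(round(window_s * tensor.frame_rate))
    if np.isnan(tensor.data).any():
        raise ValueError("trial tensor contains missing trials")
    responses = tensor.data[..., onset:onset + n_win].mean(axis=-1)
    return ResponseTable.from_array(responses, tensor.stimuli,
                                    cell_ids=tensor.cell_ids)


def correlation_matrix(table: ResponseTable) -> tuple[np.ndarray, pd.DataFrame]:
    """Pearson correlations between every pair of single-trial vectors.

    Returns the symmetric (n_trials_total, n_trials_total) matrix plus the
    per-column stimulus metadata.  Zero-variance trial vectors produce NaN
    rows/columns (reported as missing rather than raising).
    """
    mat, meta = table.matrix()            # cells x trial-vectors
    if mat.shape[0] < 2:
        raise ValueError("need >= 2 cells for trial-vector correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat.T)
    return corr, meta


def summarize_correlations(corr: np.ndarray, meta: pd.DataFrame) -> dict:
    """Mean correlation by trial-pair relationship, diagonal excluded.

    Groups: same odorant & same dilution (intra-stimulus); same odorant at
    different dilutions, keyed by the dilution pair (inter-concentration);
    different odorants.
    """
    odor = meta["odorant"].to_numpy()
    dil = meta["dilution"].to_numpy()
    n = len(meta)
    sums: dict[str, list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = corr[i, j]
            if np.isnan(v):
                continue
            if odor[i] != odor[j]:
                key = "inter_odorant"
            elif dil[i] == dil[j]:
                key = "intra_stimulus"
            else:
                lo, hi = sorted((dil[i], dil[j]))
                key = f"inter_concentration_{lo:g}_vs_{hi:g}"
            sums.setdefault(key, []).append(float(v))
    return {k: float(np.mean(v)) for k, v in sums.items()}


def lifetime_sparseness(responses: np.ndarray) -> float:
    """Selectivity of one cell's odor tuning, in [0, 1].

    Sl = (1 - (sum r_j / N)^2 / (sum r_j^2 / N)) / (1 - 1/N) over the N
    per-odor mean responses r_j.  0 for a uniform profile, 1 for a one-hot
    profile.  Negative responses are clipped to zero first (the statistic is
    defined for non-negative rates); an all-zero profile returns 0.
    """
    r = np.clip(np.asarray(responses, dtype=float), 0.0, None)
    n = r.size
    if n < 2:
        raise ValueError("need >= 2 odor responses")
    sum_sq = (r ** 2).sum()
    if sum_sq == 0:
        return 0.0
    sl = (1.0 - (r.sum() / n) ** 2 / (sum_sq / n)) / (1.0 - 1.0 / n)
    return float(sl)


def sparseness_per_cell(table: ResponseTable,
                        dilution: float | None = None) -> pd.Series:
    """Lifetime sparseness of every cell over its per-odorant mean responses.

    With ``dilution`` given, only that dilution's stimuli enter (the
    concentration-series case evaluates each dilution separately);
    otherwise every (odorant, dilution) stimulus counts as one "odor".
    """
    df = table.df
    if dilution is not None:
        df = df[df["dilution"] == dilution]
    means = df.groupby(["cell_id", "odorant", "dilution"],
                       sort=True)["response"].mean()
    return means.groupby("cell_id").apply(
        lambda r: lifetime_sparseness(r.to_numpy()))


def responsive_fractions(flags: np.ndarray) -> pd.DataFrame:
    """Percent of cells activated/suppressed per stimulus.

    ``flags`` is (n_cells, n_stimuli, n_trials) of {'act','sup','none'}; the
    percentage is the mean over trials of the fraction of flagged cells.
    """
    n_cells, n_stim, _ = flags.shape
    act = (flags == "act").mean(axis=(0, 2)) * 100.0
    sup = (flags == "sup").mean(axis=(0, 2)) * 100.0
    return pd.DataFrame({"stimulus": np.arange(n_stim),
                         "activated_pct": act, "suppressed_pct": sup})


def tuning_and_maps_filter(flags: np.ndarray, table: ResponseTable,
                           min_trials: int = 2) -> pd.DataFrame:
    """Cell-stimulus pairs responding on >= min_trials of the trials.

    Returns one row per kept (cell, stimulus) with the mean response, plus
    each cell's preferred stimulus (strongest kept mean response).
    """
    responses = table.array()                       # cells x stim x trials
    kept_counts = (flags == "act").sum(axis=2)
    keep = kept_counts >= min_trials
    stimuli = table.stimuli
    rows = []
    for c in range(responses.shape[0]):
        kept_stims = np.flatnonzero(keep[c])
        if kept_stims.size == 0:
            continue
        means = responses[c].mean(axis=1)
        pref = kept_stims[int(np.argmax(means[kept_stims]))]
        for s in kept_stims:
            rows.append({"cell_id": table.cell_ids[c],
                         "odorant": stimuli[s][0],
                         "dilution": stimuli[s][1],
                         "mean_response": means[s],
                         "preferred": s == pref})
    return pd.DataFrame(rows, columns=["cell_id", "odorant", "dilution",
                                       "mean_response", "preferred"])


def pca_project(table: ResponseTable, n_components: int = 3
                ) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of trial vectors; returns (coords, variance ratios)."""
    mat, _ = table.matrix()
    vectors = mat.T                                  # trials x cells
    if vectors.shape[0] < n_components:
        raise ValueError("fewer trials than requested components")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(vectors)
    return coords, pca.explained_variance_ratio_


def hierarchical_sort(matrix: np.ndarray) -> np.ndarray:
    """Row ordering from average-linkage clustering on (1 - Pearson) distance.

    Rows with zero variance are placed last (their correlation distance is
    undefined); a single row returns the identity ordering.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        return np.arange(matrix.shape[0])
    sd = matrix.std(axis=1)
    ok = np.flatnonzero(sd > 0)
    degenerate = np.flatnonzero(sd == 0)
    if ok.size < 2:
        return np.concatenate([ok, degenerate]).astype(int)
    link = hierarchy.linkage(matrix[ok], method="average",
                             metric="correlation")
    order = ok[hierarchy.leaves_list(link)]
    return np.concatenate([order, degenerate]).astype(int)
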