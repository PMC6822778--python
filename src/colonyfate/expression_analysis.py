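"""EB-assay relative expression and responder clustering.

ΔΔCt relative quantification (reference gene, baseline day) and k = 3
unsupervised K-means clustering of lines into Strong / Intermediate /
Weak responders per gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import AnalysisError, InputError

__all__ = [
    "ddct_log2fc",
    "cluster_responders",
    "RESPONDER_LABELS",
]

RESPONDER_LABELS = ("Strong", "Intermediate", "Weak")


def ddct_log2fc(ct: pd.DataFrame, reference_gene: str = "GAPDH",
                baseline_day: int = 0) -> pd.DataFrame:
    """ΔΔCt log₂ fold changes relative to the baseline day.

    Per (line, day, replicate): ΔCt = Ct_gene − Ct_reference; then
    ΔΔCt = ΔCt − mean ΔCt of the same (line, gene) at the baseline day;
    log₂FC = −ΔΔCt, fold change = 2^(−ΔΔCt).  Returns a long table with
    replicate-level values plus per-(line, gene, day) means.
    """
    required = {"line", "gene", "day", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise InputError(f"Ct table lacks columns {sorted(missing)}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise InputError("Ct values must be finite")
    ref = ct[ct["gene"] == reference_gene]
    tgt = ct[ct["gene"] != reference_gene].copy()
    if tgt.empty:
        raise InputError("no target genes in Ct table")
    key = ["line", "day", "replicate"]
    ref_map = ref.set_index(key)["ct"]
    if ref_map.index.has_duplicates:
        ref_map = ref_map.groupby(level=key).mean()
    idx = pd.MultiIndex.from_frame(tgt[key])
    missing_ref = ~idx.isin(ref_map.index)
    if missing_ref.any():
        line, day, _ = tgt[missing_ref].iloc[0][key]
        raise InputError(
            f"reference gene {reference_gene!r} missing for line {line!r}, day {day}")
    tgt["dct"] = tgt["ct"].to_numpy(dtype=float) - ref_map.loc[idx].to_numpy()
    base = tgt[tgt["day"] == baseline_day].groupby(["line", "gene"])["dct"].mean()
    pair_idx = pd.MultiIndex.from_frame(tgt[["line", "gene"]])
    missing_base = ~pair_idx.isin(base.index)
    if missing_base.any():
        line, gene = tgt[missing_base].iloc[0][["line", "gene"]]
        raise InputError(
            f"baseline day {baseline_day} missing for line {line!r}, gene {gene!r}")
    tgt["ddct"] = tgt["dct"].to_numpy() - base.loc[pair_idx].to_numpy()
    tgt["log2fc"] = -tgt["ddct"]
    tgt["fold_change"] = 2.0 ** tgt["log2fc"]
    means = (tgt.groupby(["line", "gene", "day"], sort=True)["log2fc"]
             .mean().rename("log2fc_mean").reset_index())
    return tgt.merge(means, on=["line", "gene", "day"], how="left")


def cluster_responders(fc: pd.DataFrame, gene: str, seed: int = 0,
                       n_init: int = 50,
                       feature_days: tuple[int, ...] | None = None
                       ) -> pd.DataFrame:
    """K-means (k = 3) Strong/Intermediate/Weak labels for one gene.

    Feature vector per line: mean log₂FC at the post-baseline days
    (default: all days > 0 present).  Labels are assigned to clusters in
    descending order of cluster-mean log₂FC, so they are content-based
    and invariant to line ordering.
    """
    sub = fc[fc["gene"] == gene]
    if sub.empty:
        raise InputError(f"gene {gene!r} not in fold-change table")
    days = feature_days if feature_days is not None else tuple(
        sorted(d for d in sub["day"].unique() if d > 0))
    if not days:
        raise InputError("no post-baseline days to cluster on")
    wide = (sub[sub["day"].isin(days)]
            .groupby(["line", "day"])["log2fc"].mean().unstack("day"))
    if wide.isna().any().any():
        raise InputError("incomplete day trajectories for some lines")
    if len(wide) < 3:
        raise AnalysisError("cluster_responders needs at least 3 lines")
    X = wide.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise AnalysisError("identical feature vectors across all lines: "
                            "degenerate input for k = 3 clustering")
    km = KMeans(n_clusters=3, n_init=n_init, random_state=seed)
    assignments = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_.mean(axis=1))
    rank_of_cluster = {int(c): r for r, c in enumerate(order)}
    labels = [RESPONDER_LABELS[rank_of_cluster[int(a)]] for a in assignments]
    out = pd.DataFrame({"line": wide.index, "label": labels,
                        "feature_mean": X.mean(axis=1)})
    out.attrs["cluster_means"] = {
        RESPONDER_LABELS[rank_of_cluster[int(c)]]: km.cluster_centers_[c].tolist()
        for c in range(3)}
    out.attrs["inertia"] = float(km.inertia_)
    return out.reset_index(drop=True)
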