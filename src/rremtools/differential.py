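"""Two-group differential (hydroxy)methylation testing.

Per-site beta-binomial Wald tests without smoothing, Benjamini-
Hochberg FDR control, and a hard effect-size filter: a locus is a DML
when its adjusted p-value is <= 0.05 and the absolute group-level
difference is >= 0.1 (both thresholds configurable and inclusive).
Significant same-direction loci are merged into regions (DMRs) by a
greedy scan with documented defaults.

The per-site variance of a pooled group proportion mu_g over
replicates i with depths d_i is

    Var_g = sum_i d_i * p~ (1 - p~) * (1 + (d_i - 1) phi) / (sum_i d_i)^2

where phi is the beta-binomial dispersion and p~ is mu_g clamped to
[1/(D+1), D/(D+1)] with D the group total depth, which keeps the
variance positive at boundary proportions.  Dispersion is estimated
per site by method of moments across replicates and shrunk toward the
genome-wide trimmed mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TestConfig:
    """Thresholds of the differential stage (all boundaries inclusive)."""

    delta: float = 0.1
    fdr_threshold: float = 0.05
    smoothing: bool = False  # fixed off; kept for config echo
    dispersion_k: float = 10.0
    dmr_min_length: int = 50
    dmr_min_cpgs: int = 3
    dmr_merge_gap: int = 100
    dmr_min_sig_fraction: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta={self.delta} outside [0, 1)")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError(f"fdr_threshold={self.fdr_threshold} outside (0, 1)")
        if self.smoothing:
            raise ValueError("smoothing is not supported (fixed off)")
        if self.dispersion_k < 0:
            raise ValueError("dispersion_k must be >= 0")
        if self.dmr_min_length < 0 or self.dmr_min_cpgs < 1:
            raise ValueError("invalid DMR size thresholds")
        if self.dmr_merge_gap < 0:
            raise ValueError("dmr_merge_gap must be >= 0")
        if not 0.0 <= self.dmr_min_sig_fraction <= 1.0:
            raise ValueError("dmr_min_sig_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# replicate matrices
# ---------------------------------------------------------------------------

def stack_replicates(count_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join replicate count tables on site, absent sites as depth 0.

    Returns a wide frame: contig, pos, then mod_i / dep_i per replicate.
    """
    if not count_tables:
        raise ValueError("need at least one replicate")
    merged = None
    for i, df in enumerate(count_tables):
        t = df[["contig", "pos", "n_modified", "depth"]].rename(
            columns={"n_modified": f"mod_{i}", "depth": f"dep_{i}"})
        merged = t if merged is None else merged.merge(t, on=["contig", "pos"],
                                                       how="outer")
    merged = merged.fillna(0)
    for c in merged.columns:
        if c.startswith(("mod_", "dep_")):
            merged[c] = merged[c].astype(np.int64)
    return merged.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)


def _split(wide: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    mods = wide[[c for c in wide.columns if c.startswith("mod_")]].to_numpy(float)
    deps = wide[[c for c in wide.columns if c.startswith("dep_")]].to_numpy(float)
    return mods, deps


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _mom_phi_group(mods: np.ndarray, deps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments beta-binomial dispersion per site for one group.

    Returns (phi_raw, weight): weight = usable replicates - 1 (0 where
    no estimate is possible; phi_raw is 0 there).
    """
    valid = deps > 0
    r = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, mods / np.where(valid, deps, 1.0), np.nan)
        pbar = np.nanmean(np.where(valid, p, np.nan), axis=1)
        s2 = np.full(mods.shape[0], np.nan)
        rows = r >= 2
        if rows.any():
            s2[rows] = np.nanvar(np.where(valid, p, np.nan)[rows], axis=1, ddof=1)
        inv_d = np.nanmean(np.where(valid, 1.0 / np.where(valid, deps, 1.0), np.nan), axis=1)
        dm1_d = np.nanmean(np.where(valid, (deps - 1.0) / np.where(valid, deps, 1.0), np.nan), axis=1)
    pq = pbar * (1.0 - pbar)
    ok = rows & (pq > 0) & (dm1_d > 0)
    phi = np.zeros(mods.shape[0])
    phi[ok] = (s2[ok] / pq[ok] - inv_d[ok]) / dm1_d[ok]
    # zero replicate variance is a legitimate phi = 0 observation
    zero_var = rows & ~ok & (s2 == 0)
    weight = np.where(rows & (ok | zero_var), r - 1, 0).astype(float)
    return phi, weight


def estimate_dispersion(mods1: np.ndarray, deps1: np.ndarray,
                        mods2: np.ndarray, deps2: np.ndarray,
                        k: float = 10.0, trim: float = 0.10,
                        ) -> np.ndarray:
    """Shrunken per-site dispersion across both groups.

    The per-site moment estimate (floored at 0) is pulled toward the
    genome-wide trimmed-mean dispersion phi_bar with weight k:
    phi_shrunk = (m * phi_site + k * phi_bar) / (m + k), where m is
    the number of replicate degrees of freedom contributing at the
    site.  k = 0 returns the pure per-site estimates.
    """
    p1, w1 = _mom_phi_group(mods1, deps1)
    p2, w2 = _mom_phi_group(mods2, deps2)
    m = w1 + w2
    with np.errstate(invalid="ignore"):
        phi_site = np.where(m > 0, (w1 * p1 + w2 * p2) / np.where(m > 0, m, 1.0), 0.0)
    phi_site = np.maximum(phi_site, 0.0)
    informative = m > 0
    phi_bar = float(stats.trim_mean(phi_site[informative], trim)) if informative.any() else 0.0
    phi_bar = max(phi_bar, 0.0)
    if k == 0:
        return phi_site
    return np.maximum((m * phi_site + k * phi_bar) / (m + k), 0.0)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def _group_stats(mods: np.ndarray, deps: np.ndarray, phi: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    D = deps.sum(axis=1)
    M = mods.sum(axis=1)
    mu = np.where(D > 0, M / np.where(D > 0, D, 1.0), np.nan)
    ptil = np.clip(mu, 1.0 / (D + 1.0), D / (D + 1.0))
    per_rep = deps * (1.0 + (deps - 1.0) * phi[:, None])
    var = (ptil * (1.0 - ptil)) * per_rep.sum(axis=1) / np.where(D > 0, D, 1.0) ** 2
    return mu, var, D


def wald_test(mods1: np.ndarray, deps1: np.ndarray,
              mods2: np.ndarray, deps2: np.ndarray,
              phi: np.ndarray) -> pd.DataFrame:
    """Per-site Wald test of pooled group levels.

    Returns mu1, mu2, diff = mu1 - mu2, se, wald_stat, p_value (two-
    sided normal).  Sites where either group has zero total depth get
    NaN statistics and are expected to be filtered upstream.
    """
    mu1, var1, d1 = _group_stats(mods1, deps1, phi)
    mu2, var2, d2 = _group_stats(mods2, deps2, phi)
    se = np.sqrt(var1 + var2)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (mu1 - mu2) / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame({"mu1": mu1, "mu2": mu2, "diff": mu1 - mu2,
                         "se": se, "wald_stat": stat, "p_value": p})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dml(records: pd.DataFrame, config: TestConfig | None = None,
             ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag DML: fdr <= threshold and |diff| >= delta (inclusive).

    Adds fdr, is_dml and direction columns; returns the table plus
    hyper/hypo counts (hyper: group 1 above group 2).
    """
    config = config or TestConfig()
    config.validate()
    out = records.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["is_dml"] = (out["fdr"] <= config.fdr_threshold) & \
                    (out["diff"].abs() >= config.delta)
    out["direction"] = np.where(out["diff"] >= 0, "hyper", "hypo")
    counts = {
        "hyper": int((out["is_dml"] & (out["direction"] == "hyper")).sum()),
        "hypo": int((out["is_dml"] & (out["direction"] == "hypo")).sum()),
    }
    return out, counts


# ---------------------------------------------------------------------------
# DMR merging
# ---------------------------------------------------------------------------

def call_dmr(records: pd.DataFrame, config: TestConfig | None = None,
             ) -> pd.DataFrame:
    """Merge significant loci into differentially methylated regions.

    A greedy scan chains consecutive same-direction significant loci
    whose inter-locus gap is <= merge_gap; a chain becomes a DMR when
    its span is >= min_length bp, it holds >= min_cpgs significant
    loci, and significant loci make up >= min_sig_fraction of all
    tested loci inside the span.  The region runs from the first to
    one past the last member position.
    """
    config = config or TestConfig()
    config.validate()
    required = {"contig", "pos", "is_dml", "direction", "diff", "wald_stat"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    for _, sub in records.groupby("contig", sort=False):
        if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
            raise ValueError("records must be sorted by position within contig")

    rows = []
    for contig, sub in records.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy()
        sig = sub[sub["is_dml"]]
        if sig.empty:
            continue
        spos = sig["pos"].to_numpy()
        sdir = sig["direction"].to_numpy()
        sdiff = sig["diff"].to_numpy()
        sstat = sig["wald_stat"].to_numpy()

        run_start = 0
        for i in range(1, len(spos) + 1):
            boundary = (i == len(spos) or sdir[i] != sdir[i - 1]
                        or spos[i] - spos[i - 1] > config.dmr_merge_gap)
            if not boundary:
                continue
            members = slice(run_start, i)
            start, end = int(spos[members][0]), int(spos[members][-1]) + 1
            n_members = i - run_start
            n_tested = int(((pos >= start) & (pos < end)).sum())
            sig_frac = n_members / n_tested if n_tested else 0.0
            if (end - start >= config.dmr_min_length
                    and n_members >= config.dmr_min_cpgs
                    and sig_frac >= config.dmr_min_sig_fraction):
                rows.append({
                    "contig": contig, "start": start, "end": end,
                    "n_cpgs": n_members,
                    "n_tested": n_tested,
                    "sig_fraction": sig_frac,
                    "mean_diff": float(sdiff[members].mean()),
                    "direction": sdir[run_start],
                    "area_stat": float(sstat[members].sum()),
                })
            run_start = i
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_cpgs",
                                       "n_tested", "sig_fraction", "mean_diff",
                                       "direction", "area_stat"])


# ---------------------------------------------------------------------------
# end-to-end two-group test
# ---------------------------------------------------------------------------

def dml_test(group1_counts: list[pd.DataFrame], group2_counts: list[pd.DataFrame],
             config: TestConfig | None = None,
             ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full locus-level differential test between two replicate sets.

    Sites must have total depth > 0 in both groups; others are dropped.
    Returns the flagged DML table (sorted by coordinate) and the
    hyper/hypo summary counts.
    """
    config = config or TestConfig()
    config.validate()
    w1 = stack_replicates(group1_counts)
    w2 = stack_replicates(group2_counts)
    sites = w1[["contig", "pos"]].merge(w2[["contig", "pos"]], on=["contig", "pos"])
    w1 = sites.merge(w1, on=["contig", "pos"], how="left").fillna(0)
    w2 = sites.merge(w2, on=["contig", "pos"], how="left").fillna(0)
    mods1, deps1 = _split(w1)
    mods2, deps2 = _split(w2)
    keep = (deps1.sum(axis=1) > 0) & (deps2.sum(axis=1) > 0)
    sites = sites[keep].reset_index(drop=True)
    mods1, deps1 = mods1[keep], deps1[keep]
    mods2, deps2 = mods2[keep], deps2[keep]
    if sites.empty:
        empty = pd.DataFrame(columns=["contig", "pos", "mu1", "mu2", "diff",
                                      "se", "wald_stat", "p_value", "fdr",
                                      "is_dml", "direction"])
        return empty, {"hyper": 0, "hypo": 0}

    phi = estimate_dispersion(mods1, deps1, mods2, deps2, k=config.dispersion_k)
    res = wald_test(mods1, deps1, mods2, deps2, phi)
    res.insert(0, "contig", sites["contig"].to_numpy())
    res.insert(1, "pos", sites["pos"].to_numpy())
    res["phi"] = phi
    flagged, counts = call_dml(res, config)
    flagged = flagged.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)
    return flagged, counts
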