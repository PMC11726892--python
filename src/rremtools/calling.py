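"""Per-CpG methylation calling, filtering and spike-in QC.

Turns site-call records into per-CpG modified/unmodified counts and
levels, applies the depth window (10-100x by default, inclusive) and
the dynamic-range window (20-80%, inclusive), estimates conversion
efficiency from the lambda/pUC19 spike-ins, and derives a 5mC-only
level from the paired RREM/RREhM assays by clipped subtraction.

Coverage tables on disk are a Bismark-coverage-compatible dialect:
header line, then contig, 1-based position, strand (+), n_modified,
n_unmodified.  In memory all coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

LAMBDA_SPIKE = "lambda_spike"
PUC19_SPIKE = "pUC19_spike"

_CALL_COLUMNS = ["read_id", "contig", "cpg_position", "observed_state"]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_site_calls(path: str | Path) -> pd.DataFrame:
    """Read a site-call TSV, rejecting malformed records by line number."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str,
                                            "observed_state": str})
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_state = ~df["observed_state"].isin(["C", "T"])
    if bad_state.any():
        lineno = int(bad_state.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed observed_state at line {lineno}")
    pos = pd.to_numeric(df["cpg_position"], errors="coerce")
    bad_pos = pos.isna() | (pos < 0) | (pos != pos.astype("Int64").astype(float))
    if bad_pos.any():
        lineno = int(bad_pos.idxmax()) + 2
        raise ValueError(f"{path}: malformed cpg_position at line {lineno}")
    df["cpg_position"] = pos.astype(np.int64)
    return df


def aggregate_counts(calls: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Tally C/T calls per CpG site.

    Returns a DataFrame with columns contig, pos, n_modified,
    n_unmodified, depth, sorted by coordinate.  Sites with no calls are
    simply absent.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = read_site_calls(calls)
    if calls.empty:
        return pd.DataFrame(columns=["contig", "pos", "n_modified",
                                     "n_unmodified", "depth"])
    g = (calls.assign(_m=calls["observed_state"].eq("C"))
              .groupby(["contig", "cpg_position"], sort=True)["_m"]
              .agg(n_modified="sum", depth="size")
              .reset_index()
              .rename(columns={"cpg_position": "pos"}))
    g["n_modified"] = g["n_modified"].astype(np.int64)
    g["depth"] = g["depth"].astype(np.int64)
    g["n_unmodified"] = g["depth"] - g["n_modified"]
    return g[["contig", "pos", "n_modified", "n_unmodified", "depth"]]


def depth_filter(counts: pd.DataFrame, lo: int = 10, hi: int = 100) -> pd.DataFrame:
    """Keep sites with lo <= depth <= hi (both ends inclusive)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    mask = (counts["depth"] >= lo) & (counts["depth"] <= hi)
    return counts[mask].reset_index(drop=True)


def with_levels(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach level = n_modified / depth."""
    out = counts.copy()
    out["level"] = out["n_modified"] / out["depth"]
    return out


def dynamic_subset(levels: pd.DataFrame, lo_frac: float = 0.20,
                   hi_frac: float = 0.80) -> pd.DataFrame:
    """Keep "dynamic" sites: lo_frac <= level <= hi_frac, inclusive."""
    if lo_frac > hi_frac:
        raise ValueError("lo_frac must be <= hi_frac")
    mask = (levels["level"] >= lo_frac) & (levels["level"] <= hi_frac)
    return levels[mask].reset_index(drop=True)


def level_histogram(levels, bin_width: float = 0.10) -> pd.DataFrame:
    """Site counts per level interval of width ``bin_width``.

    Bins are [0, w), [w, 2w), ..., with the last bin closed so a level
    of exactly 1.0 lands in it.  ``bin_width`` must divide 1 evenly.
    """
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    v = levels["level"].to_numpy(float) if isinstance(levels, pd.DataFrame) \
        else np.asarray(levels, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("levels must lie in [0, 1]")
    idx = np.minimum(np.floor(v / bin_width + 1e-9).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "count": counts})


# ---------------------------------------------------------------------------
# spike-in QC
# ---------------------------------------------------------------------------

@dataclass
class SpikeInReport:
    """Conversion-efficiency estimates from the spike-in controls.

    lambda_apparent_modification is the pooled modified fraction on the
    unmethylated lambda contig (ideally ~e_fail); for RREM the pUC19
    estimate measures protection of 5mC (ideally ~1 - e_over), while
    for RREhM pUC19's 5mC is unprotected so the estimate should again
    sit near e_fail.
    """

    assay: str
    lambda_apparent_modification: float
    lambda_ci: tuple[float, float]
    lambda_calls: int
    puc19_apparent_modification: float
    puc19_ci: tuple[float, float]
    puc19_calls: int
    n_sites: int
    lambda_warning: bool


def spikein_qc(counts: pd.DataFrame, assay: str, min_depth: int = 10,
               warn_threshold: float = 0.02) -> SpikeInReport:
    """Pooled spike-in modification estimates with Wilson 95% CIs."""
    present = set(counts["contig"].unique())
    missing = [c for c in (LAMBDA_SPIKE, PUC19_SPIKE) if c not in present]
    if missing:
        raise ValueError(f"missing spike-in contigs: {missing}")
    lam = counts[(counts["contig"] == LAMBDA_SPIKE) & (counts["depth"] >= min_depth)]
    puc = counts[(counts["contig"] == PUC19_SPIKE) & (counts["depth"] >= min_depth)]
    n_sites = len(lam) + len(puc)
    if n_sites < 20:
        raise ValueError(f"only {n_sites} spike-in sites with depth >= "
                         f"{min_depth}; need >= 20")

    lam_m, lam_d = int(lam["n_modified"].sum()), int(lam["depth"].sum())
    puc_m, puc_d = int(puc["n_modified"].sum()), int(puc["depth"].sum())
    lam_hat = lam_m / lam_d if lam_d else float("nan")
    puc_hat = puc_m / puc_d if puc_d else float("nan")
    lam_ci = proportion_confint(lam_m, lam_d, alpha=0.05, method="wilson")
    puc_ci = proportion_confint(puc_m, puc_d, alpha=0.05, method="wilson")
    return SpikeInReport(
        assay=assay,
        lambda_apparent_modification=lam_hat,
        lambda_ci=(float(lam_ci[0]), float(lam_ci[1])),
        lambda_calls=lam_d,
        puc19_apparent_modification=puc_hat,
        puc19_ci=(float(puc_ci[0]), float(puc_ci[1])),
        puc19_calls=puc_d,
        n_sites=n_sites,
        lambda_warning=bool(lam_hat > warn_threshold),
    )


# ---------------------------------------------------------------------------
# 5mC-only derivation
# ---------------------------------------------------------------------------

def estimate_5mc_only(levels_rrem: pd.DataFrame, levels_rrehm: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """5mC-only level per site: max(0, level_RREM - level_RREhM).

    Only sites covered in both assays are estimated; the report counts
    sites seen in one assay only.  No variance propagation is applied.
    """
    key = ["contig", "pos"]
    m = levels_rrem[key + ["level", "depth"]].rename(
        columns={"level": "level_rrem", "depth": "depth_rrem"})
    h = levels_rrehm[key + ["level", "depth"]].rename(
        columns={"level": "level_rrehm", "depth": "depth_rrehm"})
    merged = m.merge(h, on=key, how="outer", indicator=True)
    report = {
        "shared": int((merged["_merge"] == "both").sum()),
        "rrem_only": int((merged["_merge"] == "left_only").sum()),
        "rrehm_only": int((merged["_merge"] == "right_only").sum()),
    }
    both = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    both["level"] = np.clip(both["level_rrem"] - both["level_rrehm"], 0.0, 1.0)
    out = both[key + ["level", "level_rrem", "level_rrehm",
                      "depth_rrem", "depth_rrehm"]].reset_index(drop=True)
    return out, report


# ---------------------------------------------------------------------------
# coverage-table I/O (Bismark-coverage-compatible dialect, 1-based on disk)
# ---------------------------------------------------------------------------

_COV_HEADER = "#contig\tposition_1based\tstrand\tn_modified\tn_unmodified"


def write_coverage(counts: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COV_HEADER + "\n")
        for row in counts.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos + 1}\t+\t{row.n_modified}\t"
                     f"{row.n_unmodified}\n")


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment=None, header=0,
                     names=["contig", "pos1", "strand", "n_modified",
                            "n_unmodified"])
    out = pd.DataFrame({
        "contig": df["contig"].astype(str),
        "pos": df["pos1"].astype(np.int64) - 1,
        "n_modified": df["n_modified"].astype(np.int64),
        "n_unmodified": df["n_unmodified"].astype(np.int64),
    })
    out["depth"] = out["n_modified"] + out["n_unmodified"]
    return out
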