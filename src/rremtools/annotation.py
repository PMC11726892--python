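"""Genomic-feature annotation of CpG sites and enrichment statistics.

Overlapping raw feature intervals are flattened to one category per
base using a fixed precedence (promoter > CpG_island > exon > intron >
LINE > SINE > LTR > intergenic; intergenic is the complement).  Marked
site sets (dynamic CpGs, DMLs) are summarized as per-category
percentages and as log2 observed/expected enrichment against the
assayed background, and replicate-level enrichment values are compared
between conditions with an exact Mann-Whitney test.

With three replicates per group the smallest attainable exact
two-sided Mann-Whitney p is 2/C(6,3) = 0.1, so no significance level
below 0.1 can be reported at that replication; ``min_attainable_p``
makes the floor explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRECEDENCE = (
    "promoter", "CpG_island", "exon", "intron",
    "LINE", "SINE", "LTR", "intergenic",
)


@dataclass
class FlatAnnotation:
    """Disjoint labeling of each contig: every base has one category."""

    precedence: tuple[str, ...]
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # per contig: (starts, ends, label-codes into precedence)

    def category_of(self, contig: str, position: int) -> str:
        starts, ends, codes = self._contig(contig)
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i < 0 or position >= ends[-1]:
            raise ValueError(f"position {contig}:{position} outside contig")
        return self.precedence[codes[i]]

    def _contig(self, contig: str):
        if contig not in self.segments:
            raise ValueError(f"contig {contig!r} has no annotation")
        return self.segments[contig]


def flatten_annotation(annotation: dict[str, list[tuple[str, int, int]]],
                       contig_lengths: dict[str, int],
                       precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                       ) -> FlatAnnotation:
    """Resolve overlaps by precedence; intergenic fills the complement."""
    unknown = set(annotation) - set(precedence)
    if unknown:
        raise ValueError(f"unknown annotation categories: {sorted(unknown)}")
    if "intergenic" not in precedence:
        raise ValueError("precedence must include intergenic as fallback")
    fallback = precedence.index("intergenic")

    merged: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for cat, ivals in annotation.items():
        for contig, s, e in ivals:
            if contig not in contig_lengths:
                continue  # spike-ins and other unannotated contigs
            L = contig_lengths[contig]
            s, e = max(0, int(s)), min(L, int(e))
            if s < e:
                merged.setdefault(contig, {}).setdefault(cat, []).append((s, e))

    segments = {}
    for contig, L in contig_lengths.items():
        cats = merged.get(contig, {})
        bounds = {0, L}
        for ivals in cats.values():
            for s, e in ivals:
                bounds.update((s, e))
        cuts = np.array(sorted(bounds), dtype=np.int64)
        mids = (cuts[:-1] + cuts[1:]) / 2.0
        codes = np.full(mids.size, -1, dtype=np.int64)
        for rank, cat in enumerate(precedence):
            if cat == "intergenic" or cat not in cats:
                continue
            ivals = _merge(cats[cat])
            st = np.array([s for s, _ in ivals])
            en = np.array([e for _, e in ivals])
            j = np.searchsorted(st, mids, side="right") - 1
            inside = (j >= 0) & (mids < en[np.clip(j, 0, en.size - 1)])
            codes = np.where((codes < 0) & inside, rank, codes)
        codes[codes < 0] = fallback
        # coalesce adjacent equal labels
        keep = np.concatenate(([True], codes[1:] != codes[:-1]))
        starts = cuts[:-1][keep]
        ends = np.concatenate((starts[1:], [L]))
        segments[contig] = (starts, ends, codes[keep])
    return FlatAnnotation(precedence=tuple(precedence), segments=segments)


def _merge(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def annotate_sites(sites: pd.DataFrame, flat: FlatAnnotation) -> pd.Series:
    """One category per site; sites need contig and pos columns."""
    out = np.empty(len(sites), dtype=object)
    flat_sites = sites.reset_index(drop=True)
    for contig, sub in flat_sites.groupby("contig", sort=False):
        starts, ends, codes = flat._contig(contig)
        pos = sub["pos"].to_numpy()
        if np.any(pos < 0) or np.any(pos >= ends[-1]):
            bad = pos[(pos < 0) | (pos >= ends[-1])][0]
            raise ValueError(f"site {contig}:{bad} outside contig bounds")
        i = np.searchsorted(starts, pos, side="right") - 1
        labels = np.array(flat.precedence, dtype=object)[codes[i]]
        out[sub.index.to_numpy()] = labels
    return pd.Series(out, index=sites.index, name="category")


def distribution(categories, all_categories=DEFAULT_PRECEDENCE) -> pd.Series:
    """Percentage of sites per category (sums to 100)."""
    cats = pd.Series(list(categories))
    if cats.empty:
        raise ValueError("no sites to summarize")
    counts = cats.value_counts()
    out = pd.Series(0.0, index=list(all_categories))
    for cat, n in counts.items():
        if cat not in out.index:
            raise ValueError(f"unknown category {cat!r}")
        out[cat] = 100.0 * n / len(cats)
    return out


def log2_obs_exp(marked_categories, background_categories,
                 all_categories=DEFAULT_PRECEDENCE) -> pd.DataFrame:
    """Per-category log2(observed/expected) of a marked set vs background.

    Expected fractions are the category shares among the background
    (all assayed sites of the replicate).  Zero observed or expected
    counts are replaced by a pseudo-fraction of half a site
    (0.5/n) so the log ratio stays finite; the pseudo_used flag
    records where this happened.
    """
    marked = pd.Series(list(marked_categories))
    background = pd.Series(list(background_categories))
    if background.empty:
        raise ValueError("background must be non-empty")
    if marked.empty:
        raise ValueError("marked set must be non-empty")
    n_m, n_b = len(marked), len(background)
    rows = []
    mc = marked.value_counts()
    bc = background.value_counts()
    for cat in all_categories:
        obs_n = int(mc.get(cat, 0))
        exp_n = int(bc.get(cat, 0))
        obs_f = obs_n / n_m
        exp_f = exp_n / n_b
        pseudo = obs_n == 0 or exp_n == 0
        of = obs_f if obs_n else 0.5 / n_m
        ef = exp_f if exp_n else 0.5 / n_b
        rows.append({"category": cat, "n_observed": obs_n,
                     "observed_frac": obs_f, "expected_frac": exp_f,
                     "log2_ratio": float(np.log2(of / ef)),
                     "pseudo_used": pseudo})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney_exact(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U with an exact two-sided permutation p for small n.

    Ties take mid-ranks.  For combined n <= ``exact_max_n`` the p-value
    enumerates all label assignments and counts those at least as far
    from the null mean U = n1*n2/2 as observed; above that size the
    tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_max_n:
        dev = abs(u1 - mu)
        hits = total = 0
        base = n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        return u1, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def min_attainable_p(n1: int, n2: int) -> float:
    """Smallest exact two-sided Mann-Whitney p at the given group sizes."""
    return 2.0 / comb(n1 + n2, n1)


def compare_replicate_enrichment(enrich_a: list[pd.DataFrame],
                                 enrich_b: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-category Mann-Whitney comparison of replicate log2 ratios.

    Each input is one replicate's log2_obs_exp table.  The p_floor
    column reports the smallest attainable exact p at this replication,
    making sub-floor significance claims impossible to state.
    """
    cats = enrich_a[0]["category"].tolist()
    floor = min_attainable_p(len(enrich_a), len(enrich_b))
    rows = []
    for cat in cats:
        va = [float(df.loc[df["category"] == cat, "log2_ratio"].iloc[0])
              for df in enrich_a]
        vb = [float(df.loc[df["category"] == cat, "log2_ratio"].iloc[0])
              for df in enrich_b]
        u, p = mann_whitney_exact(va, vb)
        rows.append({"category": cat, "mean_a": float(np.mean(va)),
                     "mean_b": float(np.mean(vb)), "mw_u": u, "mw_p": p,
                     "p_floor": floor})
    return pd.DataFrame(rows)
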