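"""Window co-enrichment of a binned lesion track around candidate loci.

Scores a fixed-width window (default ±50 bp) around each locus as the
length-weighted mean of the overlapping 100-bp log2-ratio bins, then
compares the score distribution at differential loci against an
equally sized random draw of non-differential loci from the assayed
pool.  Also provides the per-chromosome summary of the track over
non-zero bins.

The track is interchange as bedGraph text; missing bins count as zero
signal (bedGraph sparsity convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class BinnedTrack:
    """Sorted, non-overlapping fixed-width bins with a float value.

    ``data`` columns: contig, start, end, value (0-based half-open).
    The last bin of a contig may be short.
    """

    data: pd.DataFrame
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = ["contig", "start", "end", "value"]
        if list(self.data.columns[:4]) != required:
            raise ValueError(f"track columns must be {required}")
        validate_track(self.data)

    @property
    def bin_width(self) -> int:
        widths = (self.data["end"] - self.data["start"]).to_numpy()
        return int(widths.max()) if widths.size else 0

    def contig_lengths(self) -> dict[str, int]:
        return {c: int(e) for c, e in self.data.groupby("contig", sort=False)["end"].max().items()}

    def contig_arrays(self, contig: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if contig not in self._arrays:
            sub = self.data[self.data["contig"] == contig]
            if sub.empty:
                raise KeyError(f"contig {contig!r} not in track")
            self._arrays[contig] = (sub["start"].to_numpy(np.int64),
                                    sub["end"].to_numpy(np.int64),
                                    sub["value"].to_numpy(float))
        return self._arrays[contig]


def validate_track(df: pd.DataFrame) -> None:
    for contig, sub in df.groupby("contig", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError(f"empty or inverted bin on {contig}")
        if starts.size > 1:
            if np.any(np.diff(starts) <= 0):
                raise ValueError(f"bins not sorted on {contig}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bins on {contig}")


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> BinnedTrack:
    """Parse a 4-column bedGraph; reject malformed lines by line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
            contig, s, e, v = parts
            try:
                rows.append((contig, int(s), int(e), float(v)))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "value"])
    return BinnedTrack(df)


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    track.data.to_csv(path, sep="\t", index=False, header=False,
                      float_format="%.6g")


# ---------------------------------------------------------------------------
# window scores
# ---------------------------------------------------------------------------

def window_score(track: BinnedTrack, contig: str, position: int,
                 half: int = 50) -> float:
    """Length-weighted mean track value over [position-half, position+half).

    The window is clipped at contig ends and the mean taken over the
    clipped length; genome not covered by any bin contributes zero.
    """
    lengths = track.contig_lengths()
    if contig not in lengths:
        raise ValueError(f"locus contig {contig!r} not in track")
    L = lengths[contig]
    if not 0 <= position < L:
        raise ValueError(f"locus {contig}:{position} outside contig (length {L})")
    w_start = max(0, position - half)
    w_end = min(L, position + half)
    if w_end <= w_start:
        raise ValueError("window has zero length")
    starts, ends, values = track.contig_arrays(contig)
    i = np.searchsorted(ends, w_start, side="right")
    j = np.searchsorted(starts, w_end, side="left")
    if i >= j:
        return 0.0
    ov = (np.minimum(ends[i:j], w_end) - np.maximum(starts[i:j], w_start)).clip(min=0)
    return float(np.dot(ov, values[i:j]) / (w_end - w_start))


def window_scores(track: BinnedTrack, loci: pd.DataFrame, half: int = 50) -> pd.DataFrame:
    """Score every locus; ``loci`` needs contig and pos columns."""
    scores = [window_score(track, c, int(p), half)
              for c, p in zip(loci["contig"], loci["pos"])]
    out = loci[["contig", "pos"]].copy()
    out["score"] = scores
    return out


# ---------------------------------------------------------------------------
# random null loci and set comparison
# ---------------------------------------------------------------------------

def sample_random_loci(pool: pd.DataFrame, exclude: pd.DataFrame | set,
                       n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Uniform sample of n loci from pool minus the exclusion set."""
    if isinstance(exclude, pd.DataFrame):
        excl = set(zip(exclude["contig"], exclude["pos"]))
    else:
        excl = set(exclude)
    keys = list(zip(pool["contig"], pool["pos"]))
    avail = [i for i, k in enumerate(keys) if k not in excl]
    if n > len(avail):
        raise ValueError(f"requested {n} loci but only {len(avail)} available "
                         "after exclusion")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(np.array(avail), size=n, replace=False)
    return pool.iloc[np.sort(chosen)][["contig", "pos"]].reset_index(drop=True)


@dataclass
class NullComparison:
    """Differential-locus scores against the random-locus null."""

    n: int
    dml_median: float
    dml_q1: float
    dml_q3: float
    random_median: float
    random_q1: float
    random_q3: float
    mw_u: float
    mw_p: float
    verdict: str  # "no co-enrichment" or "co-enrichment"


def compare_sets(dml_scores, random_scores, tau: float = 0.1) -> NullComparison:
    """Summaries, Mann-Whitney p, and the co-enrichment verdict.

    Verdict is "no co-enrichment" iff the differential-locus median is
    within ``tau`` of zero and the two score distributions are not
    distinguishable (p >= 0.05).
    """
    from .annotation import mann_whitney_exact

    d = np.asarray(dml_scores, dtype=float)
    r = np.asarray(random_scores, dtype=float)
    if d.size == 0 or r.size == 0:
        raise ValueError("score sets must be non-empty")
    u, p = mann_whitney_exact(d, r)
    no_enrich = abs(float(np.median(d))) < tau and p >= 0.05
    return NullComparison(
        n=int(d.size),
        dml_median=float(np.median(d)),
        dml_q1=float(np.percentile(d, 25)),
        dml_q3=float(np.percentile(d, 75)),
        random_median=float(np.median(r)),
        random_q1=float(np.percentile(r, 25)),
        random_q3=float(np.percentile(r, 75)),
        mw_u=float(u),
        mw_p=float(p),
        verdict="no co-enrichment" if no_enrich else "co-enrichment",
    )


# ---------------------------------------------------------------------------
# per-chromosome summary
# ---------------------------------------------------------------------------

def per_chromosome_summary(track: BinnedTrack) -> pd.DataFrame:
    """Boxplot statistics per contig over bins with value != 0.

    Whiskers follow the Tukey convention (1.5 IQR, capped at the data
    range).  A contig with no non-zero bin gets n=0 and NaN statistics.
    """
    rows = []
    for contig, sub in track.data.groupby("contig", sort=False):
        v = sub["value"].to_numpy(float)
        v = v[v != 0.0]
        if v.size == 0:
            rows.append((contig, 0, *([float("nan")] * 5)))
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = max(float(v.min()), q1 - 1.5 * iqr)
        hi = min(float(v.max()), q3 + 1.5 * iqr)
        rows.append((contig, int(v.size), float(med), float(q1), float(q3), lo, hi))
    return pd.DataFrame(rows, columns=["contig", "n_nonzero", "median",
                                       "q1", "q3", "whisker_lo", "whisker_hi"])
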