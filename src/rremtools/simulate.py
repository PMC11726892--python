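"""Synthetic study generator for paired RREM/RREhM-seq experiments.

This module builds a fully self-contained desk-scale study: a small
multi-chromosome genome with genomic-feature annotation, per-CpG
modification truth (5mC and 5hmC probabilities) with group effects, an
in-silico MspI reduced-representation digest, conversion-aware per-read
site calls for both assay chemistries, spike-in controls, and a binned
log2-ratio lesion track.

Signal model
------------
Each sequenced molecule carries, at every CpG, a latent state drawn as
5mC with probability ``p_m``, 5hmC with probability ``p_h``, otherwise
unmodified.  In the RREM chemistry both 5mC and 5hmC are protected from
deamination (they read as C); in the RREhM chemistry only 5hmC is
protected.  A protected base reads C with probability ``1 - e_over``
(``e_over`` = spurious deamination of a protected base), an unprotected
base reads C with probability ``e_fail`` (conversion failure), and a
base-call flip with probability ``e_seq`` is applied last.

Alignment is bypassed by design: reads are emitted as site-call records
with true coordinates, since mapping contributes nothing testable at
this scale.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coenrich import BinnedTrack

LAMBDA_SPIKE = "lambda_spike"
PUC19_SPIKE = "pUC19_spike"
SPIKE_CONTIGS = (LAMBDA_SPIKE, PUC19_SPIKE)

#: genomic-feature categories carried by the synthetic annotation
CATEGORIES = (
    "promoter", "exon", "intron", "intergenic",
    "CpG_island", "LINE", "SINE", "LTR",
)

ASSAYS = ("RREM", "RREhM")

_BASES = np.array(list("ACGT"))
_BG_PROBS = np.array([0.29, 0.21, 0.21, 0.29])        # ~42% GC background
_ISLAND_PROBS = np.array([0.12, 0.38, 0.38, 0.12])    # CG-rich islands


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """Contigs plus raw (possibly overlapping) feature intervals.

    ``contigs`` maps contig name to an uppercase DNA string; the two
    spike-in contigs are always present and carry no annotation.
    ``annotation`` maps category to a list of ``(contig, start, end)``
    0-based half-open intervals.
    """

    contigs: dict[str, str]
    annotation: dict[str, list[tuple[str, int, int]]]

    @property
    def main_contigs(self) -> list[str]:
        return [c for c in self.contigs if c not in SPIKE_CONTIGS]

    def contig_lengths(self, main_only: bool = True) -> dict[str, int]:
        names = self.main_contigs if main_only else list(self.contigs)
        return {c: len(self.contigs[c]) for c in names}


@dataclass
class EffectSpec:
    """A group-level shift applied to a random subset of CpGs.

    fraction: share of main-genome CpG sites affected, in [0, 1].
    target:   'p_m' or 'p_h'.
    delta:    additive shift (clipped so probabilities stay valid).
    """

    fraction: float
    target: str
    delta: float

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"effect fraction {self.fraction} outside [0, 1]")
        if self.target not in ("p_m", "p_h"):
            raise ValueError(f"effect target must be p_m or p_h, got {self.target!r}")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError(f"effect delta {self.delta} outside [-1, 1]")


def _default_effects() -> dict[str, list[EffectSpec]]:
    # AOX arms gain 5hmC, more so on the DKO background; the DKO-AOX arm
    # additionally gains some 5mC.  Magnitudes are chosen to clear the
    # differential delta threshold (0.1) at realistic depth.
    return {
        "DKO": [EffectSpec(0.02, "p_h", 0.20)],
        "WT-AOX": [EffectSpec(0.02, "p_h", 0.15)],
        "DKO-AOX": [EffectSpec(0.02, "p_h", 0.25), EffectSpec(0.01, "p_m", 0.15)],
    }


@dataclass
class StudyDesign:
    """Groups, replication, depth, effects and error rates of a run."""

    groups: tuple[str, ...] = ("WT", "DKO", "WT-AOX", "DKO-AOX")
    replicates: int = 3
    effects: dict[str, list[EffectSpec]] = field(default_factory=_default_effects)
    mean_depth: float = 30.0
    spike_depth_multiplier: float = 10.0
    e_fail: float = 0.005   # conversion failure: unprotected base reads C
    e_over: float = 0.005   # spurious deamination: protected base reads T
    e_seq: float = 0.001    # base-call flip, applied last
    seed: int = 0

    def __post_init__(self) -> None:
        # the default effect table names the default groups; a reduced
        # design silently drops effects for groups it does not carry
        self.effects = {g: v for g, v in self.effects.items() if g in self.groups}

    def validate(self) -> None:
        if len(self.groups) != len(set(self.groups)) or not self.groups:
            raise ValueError("groups must be non-empty and unique")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mean_depth <= 0 or self.spike_depth_multiplier <= 0:
            raise ValueError("depths must be positive")
        for rate, name in ((self.e_fail, "e_fail"), (self.e_over, "e_over"),
                           (self.e_seq, "e_seq")):
            if not 0.0 <= rate <= 0.5:
                raise ValueError(f"{name}={rate} outside [0, 0.5]")
        for effs in self.effects.values():
            for eff in effs:
                eff.validate()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=probs)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@functools.lru_cache(maxsize=None)
def _spike_sequence(tag_seed: int, length: int) -> str:
    """Fixed stand-in spike-in sequence: CpG-dense with regular MspI sites.

    The sequence depends only on its constant tag seed, never on the
    study seed, so spike-ins are identical across all runs.
    """
    rng = np.random.default_rng(tag_seed)
    seq = _random_dna(rng, length, _BG_PROBS)
    for q in range(10, length - 2, 40):
        seq[q:q + 2] = list("CG")
    for q in range(25, length - 5, 250):
        seq[q:q + 4] = list("CCGG")
    return "".join(seq)


def lambda_spike_sequence() -> str:
    return _spike_sequence(48502, 3000)


def puc19_spike_sequence() -> str:
    return _spike_sequence(2686, 2700)


def generate_genome(seed: int,
                    n_chromosomes: int = 2,
                    chromosome_length: int = 1_000_000,
                    island_count: int = 20,
                    repeat_density: float = 0.10) -> SyntheticGenome:
    """Generate a synthetic annotated genome plus the two spike-in contigs.

    The background sequence is CpG-depleted (80% of random CG
    dinucleotides are disrupted, mimicking the deamination-driven CpG
    deficit of mammalian genomes); MspI sites (CCGG) are planted on
    average every 500 bp so a reduced-representation digest recovers a
    usable site set; CpG islands are CG-rich rewritten segments exempt
    from depletion; genes provide promoter / exon / intron intervals
    (promoter = 1 kb upstream of the first exon); LINE/SINE/LTR
    intervals are placed at ``repeat_density`` total coverage, split
    evenly across the three repeat classes.  Deterministic for a fixed
    seed.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if chromosome_length < 10_000:
        raise ValueError("chromosome_length must be >= 10000")
    if island_count < 0:
        raise ValueError("island_count must be >= 0")
    if not 0.0 <= repeat_density <= 0.5:
        raise ValueError("repeat_density must be in [0, 0.5]")

    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    ann: dict[str, list[tuple[str, int, int]]] = {c: [] for c in CATEGORIES}
    L = chromosome_length

    for ci in range(n_chromosomes):
        name = f"chr{ci + 1}"
        seq = _random_dna(rng, L, _BG_PROBS)

        # CpG depletion of the background: disrupt 80% of CG dinucleotides
        a = np.frombuffer("".join(seq).encode("ascii"), dtype=np.uint8)
        cg = np.flatnonzero((a[:-1] == ord("C")) & (a[1:] == ord("G")))
        kill = cg[rng.random(cg.size) < 0.8]
        seq[kill + 1] = rng.choice(np.array(list("AT")), size=kill.size)

        n_cut = max(1, L // 500)
        cut_pos = np.sort(rng.choice(L - 4, size=n_cut, replace=False))
        for p in cut_pos:
            seq[p:p + 4] = list("CCGG")

        for _ in range(island_count):
            ilen = int(rng.integers(600, 1500))
            s = int(rng.integers(0, L - ilen))
            seg = _random_dna(rng, ilen, _ISLAND_PROBS)
            for q in range(6, ilen - 2, 14):
                seg[q:q + 2] = list("CG")
            for q in range(25, ilen - 5, 300):
                seg[q:q + 4] = list("CCGG")
            seq[s:s + ilen] = seg
            ann["CpG_island"].append((name, s, s + ilen))

        # gene structures: promoter + alternating exon/intron blocks
        pos = 1500
        while pos < L - 20_000:
            gstart = pos + int(rng.integers(2000, 12_000))
            n_ex = int(rng.integers(3, 7))
            exons: list[tuple[int, int]] = []
            cur = gstart
            for e in range(n_ex):
                elen = int(rng.integers(150, 300))
                exons.append((cur, cur + elen))
                cur += elen
                if e < n_ex - 1:
                    cur += int(rng.integers(500, 3000))
            if cur > L - 1500:
                break
            ann["promoter"].append((name, max(0, gstart - 1000), gstart))
            for s, e in exons:
                ann["exon"].append((name, s, e))
            for (_, e1), (s2, _) in zip(exons, exons[1:]):
                ann["intron"].append((name, e1, s2))
            pos = cur

        for cat, alen in (("LINE", 3000), ("SINE", 200), ("LTR", 500)):
            n_rep = int(repeat_density * L / (3 * alen))
            for _ in range(n_rep):
                rl = int(rng.integers(int(alen * 0.7), int(alen * 1.3)))
                s = int(rng.integers(0, L - rl))
                ann[cat].append((name, s, s + rl))

        contigs[name] = "".join(seq)

    # raw intergenic = complement of gene-associated intervals
    genic = ann["promoter"] + ann["exon"] + ann["intron"]
    for name in contigs:
        merged = _merge_intervals([(s, e) for c, s, e in genic if c == name])
        prev = 0
        for s, e in merged:
            if s > prev:
                ann["intergenic"].append((name, prev, s))
            prev = max(prev, e)
        if prev < L:
            ann["intergenic"].append((name, prev, L))

    contigs[LAMBDA_SPIKE] = lambda_spike_sequence()
    contigs[PUC19_SPIKE] = puc19_spike_sequence()
    return SyntheticGenome(contigs=contigs, annotation=ann)


def find_cpg_sites(sequence: str) -> np.ndarray:
    """0-based positions of the C of every plus-strand CpG."""
    a = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    if a.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((a[:-1] == ord("C")) & (a[1:] == ord("G"))).astype(np.int64)


# ---------------------------------------------------------------------------
# MspI digest
# ---------------------------------------------------------------------------

def mspi_fragments(sequence: str) -> list[tuple[int, int]]:
    """All fragments of a complete MspI digest (no size selection).

    MspI cuts C^CGG; the single per-occurrence cut coordinate is one
    base into the motif.  The fragments tile the input exactly.
    """
    cuts: list[int] = []
    i = sequence.find("CCGG")
    while i != -1:
        cuts.append(i + 1)
        i = sequence.find("CCGG", i + 1)
    bounds = [0] + cuts + [len(sequence)]
    return [(s, e) for s, e in zip(bounds, bounds[1:]) if e > s]


def digest_mspi(sequence: str, min_len: int = 40, max_len: int = 400) -> list[tuple[int, int]]:
    """Size-selected MspI fragments (both bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if min_len < 0:
        raise ValueError("fragment bounds must be non-negative")
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return [(s, e) for s, e in mspi_fragments(sequence) if min_len <= e - s <= max_len]


def digest_genome(genome: SyntheticGenome, min_len: int = 40,
                  max_len: int = 400) -> dict[str, list[tuple[int, int]]]:
    return {name: digest_mspi(seq, min_len, max_len)
            for name, seq in genome.contigs.items()}


# ---------------------------------------------------------------------------
# modification truth
# ---------------------------------------------------------------------------

def generate_truth(genome: SyntheticGenome, design: StudyDesign,
                   ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-group truth tables plus a ledger of applied effects.

    Baseline ``p_m`` is a two-component beta mixture (75% of sites from
    Beta(0.4, 15), the rest from Beta(5, 5)) so the bulk of sites sit
    below 10% methylation with a minority of intermediate, "dynamic"
    sites.  Baseline ``p_h`` is Beta(0.5, 24.5) (mean 0.02).  Spike-in
    truth is idealized: lambda fully unmodified; pUC19 fully
    CpG-methylated.  Group effects are applied to seeded random site
    subsets and recorded in the returned ledger with both the requested
    and the realized (post-clipping) delta.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    frames = []
    for name, seq in genome.contigs.items():
        pos = find_cpg_sites(seq)
        n = pos.size
        if name == LAMBDA_SPIKE:
            p_m = np.zeros(n)
            p_h = np.zeros(n)
        elif name == PUC19_SPIKE:
            p_m = np.ones(n)
            p_h = np.zeros(n)
        else:
            low = rng.random(n) < 0.75
            p_m = np.where(low, rng.beta(0.4, 15.0, n), rng.beta(5.0, 5.0, n))
            p_h = rng.beta(0.5, 24.5, n)
            p_h = np.minimum(p_h, 1.0 - p_m)
        frames.append(pd.DataFrame({"contig": name, "pos": pos,
                                    "p_m": p_m, "p_h": p_h}))
    base = pd.concat(frames, ignore_index=True)
    main_idx = np.flatnonzero(~base["contig"].isin(SPIKE_CONTIGS).to_numpy())
    n_main = main_idx.size

    truths: dict[str, pd.DataFrame] = {}
    ledger_rows = []
    for grp in design.groups:
        t = base.copy()
        for eff in design.effects.get(grp, []):
            n_aff = int(round(eff.fraction * n_main))
            if n_aff == 0:
                continue
            idx = rng.choice(main_idx, size=n_aff, replace=False)
            tgt = t[eff.target].to_numpy().copy()
            other = t["p_h" if eff.target == "p_m" else "p_m"].to_numpy()
            old = tgt[idx].copy()
            new = np.clip(tgt[idx] + eff.delta, 0.0, 1.0)
            new = np.minimum(new, 1.0 - other[idx])  # keep p_m + p_h <= 1
            tgt[idx] = new
            t[eff.target] = tgt
            led = pd.DataFrame({
                "contig": t["contig"].to_numpy()[idx],
                "pos": t["pos"].to_numpy()[idx],
                "group": grp,
                "target": eff.target,
                "delta_requested": eff.delta,
                "delta_realized": new - old,
            })
            ledger_rows.append(led)
        truths[grp] = t
    ledger = (pd.concat(ledger_rows, ignore_index=True) if ledger_rows
              else pd.DataFrame(columns=["contig", "pos", "group", "target",
                                         "delta_requested", "delta_realized"]))
    return truths, ledger


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def protected_probability(p_m, p_h, assay: str):
    if assay == "RREM":
        return np.asarray(p_m) + np.asarray(p_h)
    if assay == "RREhM":
        return np.asarray(p_h)
    raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")


def expected_level(p_m, p_h, assay: str, design: StudyDesign) -> np.ndarray:
    """Expected observed-C fraction at a site under the error model."""
    prot = protected_probability(p_m, p_h, assay)
    q_prot = (1 - design.e_over) * (1 - design.e_seq) + design.e_over * design.e_seq
    q_unprot = design.e_fail * (1 - design.e_seq) + (1 - design.e_fail) * design.e_seq
    return q_prot * prot + q_unprot * (1 - prot)


def covered_sites(fragments: list[tuple[int, int]], positions: np.ndarray) -> np.ndarray:
    """Boolean mask of CpG positions whose dinucleotide lies inside a fragment."""
    if not fragments or positions.size == 0:
        return np.zeros(positions.size, dtype=bool)
    starts = np.array([s for s, _ in fragments])
    ends = np.array([e for _, e in fragments])
    k = np.searchsorted(starts, positions, side="right") - 1
    kk = np.clip(k, 0, starts.size - 1)
    return (k >= 0) & (positions + 2 <= ends[kk])


def simulate_reads(fragments: dict[str, list[tuple[int, int]]],
                   truth: pd.DataFrame,
                   assay: str,
                   design: StudyDesign,
                   rng: np.random.Generator | None = None,
                   read_offset: int = 0) -> pd.DataFrame:
    """Simulate one library as per-CpG site-call records.

    Per-site depth is Poisson with the design mean (times the spike-in
    multiplier on spike contigs); per-molecule latent states and
    conversion/sequencing errors follow the module signal model.
    Returns a DataFrame with columns read_id, contig, cpg_position,
    observed_state.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if rng is None:
        rng = np.random.default_rng(design.seed)

    q_prot = (1 - design.e_over) * (1 - design.e_seq) + design.e_over * design.e_seq
    q_unprot = design.e_fail * (1 - design.e_seq) + (1 - design.e_fail) * design.e_seq

    out_frames = []
    serial = read_offset
    for contig, frs in fragments.items():
        sub = truth[truth["contig"] == contig]
        if sub.empty or not frs:
            continue
        pos = sub["pos"].to_numpy()
        mask = covered_sites(frs, pos)
        if not mask.any():
            continue
        pos = pos[mask]
        p_m = sub["p_m"].to_numpy()[mask]
        p_h = sub["p_h"].to_numpy()[mask]

        mean_depth = design.mean_depth
        if contig in SPIKE_CONTIGS:
            mean_depth *= design.spike_depth_multiplier
        d = rng.poisson(mean_depth, size=pos.size)
        nz = d > 0
        pos, p_m, p_h, d = pos[nz], p_m[nz], p_h[nz], d[nz]
        if pos.size == 0:
            continue

        n_m = rng.binomial(d, p_m)
        rem = d - n_m
        denom = 1.0 - p_m
        cond_h = np.divide(p_h, denom, out=np.zeros_like(p_h), where=denom > 0)
        n_h = rng.binomial(rem, np.clip(cond_h, 0.0, 1.0))
        prot = (n_m + n_h) if assay == "RREM" else n_h
        unprot = d - prot
        n_c = rng.binomial(prot, q_prot) + rng.binomial(unprot, q_unprot)

        total = int(d.sum())
        cum = np.cumsum(d) - d
        offset_in_site = np.arange(total) - np.repeat(cum, d)
        state = np.where(offset_in_site < np.repeat(n_c, d), "C", "T")
        out_frames.append(pd.DataFrame({
            "read_id": [f"r{j}" for j in range(serial, serial + total)],
            "contig": np.repeat(np.full(pos.size, contig, dtype=object), d),
            "cpg_position": np.repeat(pos, d),
            "observed_state": state,
        }))
        serial += total

    if not out_frames:
        return pd.DataFrame(columns=["read_id", "contig", "cpg_position",
                                     "observed_state"])
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# lesion track
# ---------------------------------------------------------------------------

def simulate_lesion_track(genome: SyntheticGenome,
                          bin_width: int = 100,
                          enriched_regions: list[tuple[str, int, int]] = (),
                          effect: float = 0.0,
                          noise_sd: float = 0.25,
                          seed: int = 0) -> BinnedTrack:
    """Binned log2-ratio lesion track over the main chromosomes.

    Bin values are Normal(0, noise_sd); ``effect`` is added to every
    bin overlapping an enriched region (additively per region).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lengths = genome.contig_lengths(main_only=True)
    for c, s, e in enriched_regions:
        if c not in lengths or s < 0 or e > lengths[c] or s >= e:
            raise ValueError(f"enriched region ({c}, {s}, {e}) outside genome")

    rng = np.random.default_rng(seed)
    frames = []
    for contig, L in lengths.items():
        starts = np.arange(0, L, bin_width)
        ends = np.minimum(starts + bin_width, L)
        vals = rng.normal(0.0, noise_sd, starts.size) if noise_sd > 0 else np.zeros(starts.size)
        for c, s, e in enriched_regions:
            if c == contig:
                vals = vals + effect * ((starts < e) & (ends > s))
        frames.append(pd.DataFrame({"contig": contig, "start": starts,
                                    "end": ends, "value": vals}))
    return BinnedTrack(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# on-disk artifacts
# ---------------------------------------------------------------------------

def write_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.contigs.items()]
    seqio_write(records, str(path), "fasta")


def write_annotation_beds(genome: SyntheticGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cat, ivals in genome.annotation.items():
        with open(outdir / f"{cat}.bed", "w") as fh:
            for contig, s, e in sorted(ivals):
                fh.write(f"{contig}\t{s}\t{e}\t{cat}\n")


def write_site_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def write_truth(truths: dict[str, pd.DataFrame], ledger: pd.DataFrame,
                outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for grp, t in truths.items():
        t.to_csv(outdir / f"truth_{grp}.tsv", sep="\t", index=False,
                 float_format="%.6g")
    ledger.to_csv(outdir / "truth_ledger.tsv", sep="\t", index=False,
                  float_format="%.6g")


def write_design(design: StudyDesign, path: str | Path) -> None:
    """Echo the design as a flat key=value config file."""
    effects = ";".join(
        f"{grp}:{eff.target}:{eff.fraction}:{eff.delta}"
        for grp, effs in design.effects.items() for eff in effs
    ) or "none"
    lines = [
        f"groups={','.join(design.groups)}",
        f"replicates={design.replicates}",
        f"effects={effects}",
        f"mean_depth={design.mean_depth}",
        f"spike_depth_multiplier={design.spike_depth_multiplier}",
        f"e_fail={design.e_fail}",
        f"e_over={design.e_over}",
        f"e_seq={design.e_seq}",
        f"seed={design.seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
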