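"""Seeded generators for every input the atlas pipeline consumes.

The generators emulate the raw material of an invertebrate DNA-methylation
survey: CpG-depleted transcriptomes (first-order Markov chains calibrated to
a target CpG o/e), genomes with placed CCGG/GAATTC restriction sites and a
binary per-site methylation truth, bisulfite-converted read sets over a
locus, noisy pyrosequencing peak profiles, and gene-family count matrices
evolved down a species tree under a single-gain (Dollo-compatible)
loss/duplication model.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

import dendropy

__all__ = [
    "SequenceRecord",
    "Genome",
    "MethylomeTrack",
    "BisulfiteReadSet",
    "SimulationConfig",
    "PlacementError",
    "simulate_transcriptome",
    "simulate_genome_with_sites",
    "assign_ccgg_methylation",
    "simulate_bisulfite_reads",
    "add_pyrogram_noise",
    "simulate_repertoire_evolution",
]

_ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(_ALPHABET)}


class PlacementError(ValueError):
    """Requested restriction-site layout cannot fit in the genome."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not set(self.residues) <= set("ACGTN"):
            bad = sorted(set(self.residues) - set("ACGTN"))
            raise ValueError(f"sequence {self.id!r} contains non-ACGTN residues: {bad}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Genome:
    """A linear, single-contig genome with declared restriction-site counts.

    The declared counts are guaranteed exact: a motif scan of ``record``
    finds precisely ``declared_ccgg_count`` CCGG and ``declared_ecori_count``
    GAATTC occurrences and no others.
    """

    record: SequenceRecord
    declared_ccgg_count: int
    declared_ecori_count: int
    ccgg_positions: tuple[int, ...] = ()
    ecori_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class MethylomeTrack:
    """Binary methylation state for each CCGG site of a genome."""

    site_positions: tuple[int, ...]
    methylated: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.site_positions) != len(self.methylated):
            raise ValueError("one methylation flag required per site position")
        if any(b >= a for a, b in zip(self.site_positions[1:], self.site_positions)):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def n_methylated(self) -> int:
        return sum(self.methylated)


@dataclass(frozen=True)
class BisulfiteReadSet:
    """Pre-aligned bisulfite reads over a reference locus."""

    reference: SequenceRecord
    cpg_positions: tuple[int, ...]
    reads: tuple[str, ...]
    conversion_rate: float
    error_rate: float

    def __post_init__(self) -> None:
        L = self.reference.length
        if any(len(r) != L for r in self.reads):
            raise ValueError("all reads must have the same length as the reference")
        for p in self.cpg_positions:
            if not (self.reference.residues[p] == "C" and p + 1 < L and self.reference.residues[p + 1] == "G"):
                raise ValueError(f"position {p} is not the C of a CpG in the reference")


@dataclass
class SimulationConfig:
    """Seed plus free-form generator parameters; serialisable to JSON."""

    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        return cls(seed=d["seed"], params=d.get("params", {}))


# ---------------------------------------------------------------------------
# transcriptome generator
# ---------------------------------------------------------------------------

def _markov_matrix(gc: float, target_oe: float) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix and stationary distribution of the calibrated chain.

    Background composition is strand-symmetric iid with the given GC content.
    Only the C row deviates from iid: its C->G probability q is set by a
    fixed-point so that the expected CpG o/e under the chain's *stationary*
    distribution equals ``target_oe`` exactly (q = target_oe * pi_G, with
    pi_G itself a function of q). The remaining C-row mass is spread over
    A/C/T proportionally to the background.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    if target_oe <= 0:
        raise ValueError("target_oe must be positive")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    pG = p[_IDX["G"]]
    q = target_oe * pG
    for _ in range(200):
        if q >= 1.0:
            raise ValueError(
                f"target_oe={target_oe} requires CG transition probability {q:.3f} >= 1"
            )
        # only row C is modified, so the stationary chain has a closed form
        pCC = p[_IDX["C"]] * (1 - q) / (1 - pG)
        piC = p[_IDX["C"]] / (1 + p[_IDX["C"]] - pCC)
        piG = (1 - piC) * pG + piC * q
        q_new = target_oe * piG
        if abs(q_new - q) < 1e-14:
            q = q_new
            break
        q = q_new
    if q >= 1.0:
        raise ValueError(
            f"target_oe={target_oe} requires CG transition probability {q:.3f} >= 1"
        )
    T = np.tile(p, (4, 1))
    rowC = p * (1 - q) / (1 - pG)
    rowC[_IDX["G"]] = q
    T[_IDX["C"]] = rowC
    piC = p[_IDX["C"]] / (1 + p[_IDX["C"]] - rowC[_IDX["C"]])
    pi = (1 - piC) * p + piC * rowC
    pi[_IDX["C"]] = piC
    pi = pi / pi.sum()
    return T, pi


def simulate_transcriptome(
    n: int,
    length_range: tuple[int, int],
    gc: float,
    target_oe: float,
    seed: int,
) -> list[SequenceRecord]:
    """Draw ``n`` transcripts from a Markov chain calibrated to a CpG o/e.

    Parameters
    ----------
    n : number of transcripts (>= 1).
    length_range : inclusive (min, max) transcript length in bp.
    gc : stationary GC content of the background composition.
    target_oe : expected per-transcript CpG observed/expected ratio.
    seed : RNG seed; identical inputs give identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi <= 10**6):
        raise ValueError("length_range must satisfy 1 <= min <= max <= 1e6")
    T, pi = _markov_matrix(gc, target_oe)
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    L = int(lengths.max())
    cumT = np.cumsum(T, axis=1)
    cum_pi = np.cumsum(pi)
    states = np.empty((n, L), dtype=np.int8)
    states[:, 0] = np.searchsorted(cum_pi, rng.random(n))
    for j in range(1, L):
        u = rng.random(n)
        states[:, j] = (u[:, None] > cumT[states[:, j - 1]]).sum(axis=1)
    letters = np.frombuffer(_ALPHABET.encode(), dtype="S1")
    out = []
    for i in range(n):
        seq = letters[states[i, : lengths[i]]].tobytes().decode()
        out.append(SequenceRecord(id=f"tx{i:05d}", residues=seq))
    return out


# ---------------------------------------------------------------------------
# genome with placed restriction sites
# ---------------------------------------------------------------------------

_CCGG = "CCGG"
_ECORI = "GAATTC"


def _scan(seq: str, motif: str) -> list[int]:
    # overlapping scan; independent of restriction_luma.find_sites
    return [m.start() for m in re.finditer(f"(?={re.escape(motif)})", seq)]


def simulate_genome_with_sites(
    length: int,
    n_ccgg: int,
    n_ecori: int,
    gc: float,
    seed: int,
) -> Genome:
    """Generate a linear genome with exact counts of CCGG and GAATTC sites.

    Motifs are placed non-overlapping at seeded random positions; the
    background is then repaired (single-base mutations outside the placed
    motifs) until a scan finds no accidental extra occurrence of either
    motif. Raises :class:`PlacementError` when the motifs cannot fit.
    """
    if n_ccgg < 0 or n_ecori < 0:
        raise ValueError("site counts must be non-negative")
    total = 4 * n_ccgg + 6 * n_ecori
    if total > length:
        raise PlacementError(
            f"{n_ccgg} CCGG + {n_ecori} GAATTC need {total} bp but genome is {length} bp"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(_ALPHABET.encode(), dtype="S1"), size=length, p=p)

    motifs = [_CCGG] * n_ccgg + [_ECORI] * n_ecori
    rng.shuffle(motifs)
    k = len(motifs)
    starts: list[int] = []
    if k:
        free = length - total
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        offset = 0
        for g, m in zip(gaps, motifs):
            starts.append(int(g) + offset)
            offset += len(m)
    for s, m in zip(starts, motifs):
        arr[s : s + len(m)] = np.frombuffer(m.encode(), dtype="S1")

    protected = np.zeros(length, dtype=bool)
    for s, m in zip(starts, motifs):
        protected[s : s + len(m)] = True
    intended_ccgg = {s for s, m in zip(starts, motifs) if m == _CCGG}
    intended_ecori = {s for s, m in zip(starts, motifs) if m == _ECORI}

    letters = np.frombuffer(_ALPHABET.encode(), dtype="S1")
    for _ in range(10_000):
        seq = arr.tobytes().decode()
        extras = [
            (s, _CCGG) for s in _scan(seq, _CCGG) if s not in intended_ccgg
        ] + [
            (s, _ECORI) for s in _scan(seq, _ECORI) if s not in intended_ecori
        ]
        if not extras:
            break
        for s, m in extras:
            mutable = [i for i in range(s, s + len(m)) if not protected[i]]
            if not mutable:  # cannot occur with these motifs, defensive
                raise PlacementError("accidental motif fully inside placed sites")
            i = mutable[rng.integers(len(mutable))]
            choices = letters[letters != arr[i]]
            arr[i] = choices[rng.integers(len(choices))]
    else:
        raise PlacementError("could not repair background to exact motif counts")

    seq = arr.tobytes().decode()
    ccgg = tuple(_scan(seq, _CCGG))
    ecori = tuple(_scan(seq, _ECORI))
    assert len(ccgg) == n_ccgg and len(ecori) == n_ecori
    return Genome(
        record=SequenceRecord(id="synthetic_genome", residues=seq),
        declared_ccgg_count=n_ccgg,
        declared_ecori_count=n_ecori,
        ccgg_positions=ccgg,
        ecori_positions=ecori,
    )


def assign_ccgg_methylation(genome: Genome, fraction: float, seed: int) -> MethylomeTrack:
    """Flag an exact ``round(fraction * n_sites)`` subset of CCGG sites.

    Sites are chosen uniformly without replacement, so noise-free recovery
    of the methylated percentage is exact rather than binomially scattered.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    positions = genome.ccgg_positions
    n = len(positions)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False).tolist()) if n else set()
    return MethylomeTrack(
        site_positions=tuple(positions),
        methylated=tuple(i in chosen for i in range(n)),
    )


# ---------------------------------------------------------------------------
# bisulfite forward model
# ---------------------------------------------------------------------------

def simulate_bisulfite_reads(
    locus: SequenceRecord,
    per_cpg_m: Sequence[float],
    n_reads: int,
    conversion_rate: float,
    error_rate: float,
    seed: int,
) -> BisulfiteReadSet:
    """Forward-simulate bisulfite conversion of reads over a locus.

    Per read, each CpG cytosine is methylated with its site probability;
    methylated C stays C, unmethylated C (CpG or not) converts to T with
    probability ``conversion_rate``. Uniform substitution noise at
    ``error_rate`` is applied afterwards.
    """
    if locus.length == 0:
        raise ValueError("locus is empty")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    ref = locus.residues
    cpg_positions = tuple(
        i for i in range(len(ref) - 1) if ref[i] == "C" and ref[i + 1] == "G"
    )
    if len(per_cpg_m) != len(cpg_positions):
        raise ValueError(
            f"per_cpg_m has {len(per_cpg_m)} entries but locus has {len(cpg_positions)} CpGs"
        )
    rng = np.random.default_rng(seed)
    L = len(ref)
    base = np.frombuffer(ref.encode(), dtype="S1")
    reads = np.tile(base, (n_reads, 1))

    c_mask = base == b"C"
    cpg_idx = np.array(cpg_positions, dtype=int)
    non_cpg_c = np.where(c_mask)[0]
    non_cpg_c = non_cpg_c[~np.isin(non_cpg_c, cpg_idx)]

    if len(cpg_idx):
        m = np.asarray(per_cpg_m, dtype=float)
        methylated = rng.random((n_reads, len(cpg_idx))) < m
        convert = (~methylated) & (rng.random((n_reads, len(cpg_idx))) < conversion_rate)
        cols = np.broadcast_to(cpg_idx, convert.shape)
        reads[np.where(convert)[0], cols[convert]] = b"T"
    if len(non_cpg_c):
        convert = rng.random((n_reads, len(non_cpg_c))) < conversion_rate
        cols = np.broadcast_to(non_cpg_c, convert.shape)
        reads[np.where(convert)[0], cols[convert]] = b"T"

    if error_rate > 0:
        err = rng.random((n_reads, L)) < error_rate
        letters = np.frombuffer(_ALPHABET.encode(), dtype="S1")
        letters_u8 = letters.view(np.uint8)
        where = np.where(err)
        # substitute with one of the 3 letters != current, by index shifting
        cur_idx = np.searchsorted(letters_u8, reads[where].view(np.uint8))
        repl_idx = rng.integers(0, 3, size=len(where[0]))
        repl_idx = repl_idx + (repl_idx >= cur_idx)
        reads[where] = letters[repl_idx]

    read_strings = tuple(reads[i].tobytes().decode() for i in range(n_reads))
    return BisulfiteReadSet(
        reference=locus,
        cpg_positions=cpg_positions,
        reads=read_strings,
        conversion_rate=conversion_rate,
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# pyrogram noise
# ---------------------------------------------------------------------------

def add_pyrogram_noise(pyro, cv: float, seed: int):
    """Multiplicative truncated-Gaussian noise on peak heights.

    Each peak is multiplied by an independent factor with mean 1 and
    coefficient of variation ``cv``; negative outcomes clamp to 0, modelling
    proportional pyrosequencing light-intensity noise.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    from .restriction_luma import Pyrogram  # local import avoids a cycle

    peaks = np.asarray(pyro.peaks, dtype=float)
    if cv == 0:
        return Pyrogram(reaction=pyro.reaction, peaks=tuple(peaks))
    rng = np.random.default_rng(seed)
    factors = rng.normal(1.0, cv, size=peaks.shape)
    noisy = np.clip(peaks * factors, 0.0, None)
    return Pyrogram(reaction=pyro.reaction, peaks=tuple(noisy))


# ---------------------------------------------------------------------------
# repertoire evolution on a tree
# ---------------------------------------------------------------------------

def simulate_repertoire_evolution(
    tree: dendropy.Tree,
    families: Sequence[str],
    root_counts: Sequence[int],
    loss_rate: float,
    dup_rate: float,
    seed: int,
):
    """Evolve per-family gene counts down a rooted species tree.

    On each edge a family present in the parent is lost outright with
    probability ``loss_rate``, otherwise its count is incremented with
    probability ``dup_rate``. A family never re-appears after loss, so the
    resulting leaf matrices are Dollo-compatible by construction.
    """
    from .repertoire import RepertoireMatrix

    if not tree.is_rooted:
        raise ValueError("repertoire evolution requires a rooted tree")
    if not (0.0 <= loss_rate <= 1.0 and 0.0 <= dup_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if len(root_counts) != len(families):
        raise ValueError("one root count per family required")
    if any(c < 1 for c in root_counts):
        raise ValueError("root counts must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[int, np.ndarray] = {id(tree.seed_node): np.asarray(root_counts, dtype=int)}
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            vec = counts[id(node)]
        else:
            parent = counts[id(node.parent_node)]
            vec = parent.copy()
            alive = vec > 0
            lost = alive & (rng.random(len(vec)) < loss_rate)
            vec[lost] = 0
            dup = (vec > 0) & (rng.random(len(vec)) < dup_rate)
            vec[dup] += 1
            counts[id(node)] = vec
        if node.is_leaf():
            rows[node.taxon.label] = vec
    import pandas as pd

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(families))
    return RepertoireMatrix(df)
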