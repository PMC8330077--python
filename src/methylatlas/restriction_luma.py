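"""In-silico methylation-sensitive restriction digestion and LUMA.

HpaII and MspI are isoschizomers cutting C^CGG; HpaII is blocked when the
internal CpG of the site is methylated while MspI cuts regardless. EcoRI
(G^AATTC) is methylation-indifferent and serves as the input normaliser.
Pyrosequencing fill-in of the digestion overhangs produces light peaks
whose ratios quantify cut sites: each CCGG cut exposes two 5'-CG overhangs
(one C + one G incorporation per end), each EcoRI cut two 5'-AATT overhangs
(two A + two T per end). With the dispensation order

    dATP; dGTP+dCTP; dTTP; H2O (control); dGTP+dCTP; dATP; dTTP

the per-reaction ratio is (dGTP+dCTP) / mean(dATP, dTTP) and the percentage
of methylated CCGG sites is 100 * [1 - (HpaII/EcoRI) / (MspI/EcoRI)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import Genome, MethylomeTrack, SequenceRecord, add_pyrogram_noise

__all__ = [
    "DISPENSATION_ORDER",
    "DigestResult",
    "GelProfile",
    "Pyrogram",
    "LumaResult",
    "LumaError",
    "find_sites",
    "digest",
    "virtual_gel",
    "pyrogram_from_digest",
    "luma_ratio",
    "luma_percent_methylation",
    "estimate_percent_methylation",
]

DISPENSATION_ORDER: tuple[str, ...] = (
    "dATP",
    "dGTP+dCTP",
    "dTTP",
    "H2O",
    "dGTP+dCTP",
    "dATP",
    "dTTP",
)

_ENZYMES = {"HpaII", "MspI", "EcoRI", "HpaII+EcoRI", "MspI+EcoRI"}


class LumaError(ValueError):
    """Raised when the LUMA estimator is undefined (failed EcoRI control)."""


@dataclass(frozen=True)
class DigestResult:
    enzyme: str
    cut_positions: tuple[int, ...]  # 0-based between-base indices
    fragment_lengths: tuple[int, ...]
    ccgg_cuts: int
    ecori_cuts: int


@dataclass(frozen=True)
class GelProfile:
    bin_edges: np.ndarray  # log-spaced, bp
    mass_per_bin: np.ndarray  # length-weighted


@dataclass(frozen=True)
class Pyrogram:
    reaction: str  # "HpaII+EcoRI" or "MspI+EcoRI"
    peaks: tuple[float, ...]  # one per dispensation, length 7

    def __post_init__(self) -> None:
        if len(self.peaks) != len(DISPENSATION_ORDER):
            raise ValueError(f"pyrogram must have {len(DISPENSATION_ORDER)} peaks")

    @property
    def dispensations(self) -> tuple[str, ...]:
        return DISPENSATION_ORDER


@dataclass(frozen=True)
class LumaResult:
    ratio_hpaii: float
    ratio_mspi: float
    percent_methylation: float
    raw_percent: float
    clamped: bool


def find_sites(seq: SequenceRecord | str, motif: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) motif matches."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if not set(motif) <= set("ACGT"):
        raise ValueError(f"motif {motif!r} must be over A/C/G/T")
    s = seq if isinstance(seq, str) else seq.residues
    out: list[int] = []
    i = s.find(motif)
    while i != -1:
        out.append(i)
        i = s.find(motif, i + 1)
    return out


def digest(
    genome: Genome,
    enzyme: str,
    methylome: MethylomeTrack | None = None,
) -> DigestResult:
    """Digest a linear genome, honouring HpaII's methylation sensitivity.

    MspI cuts every CCGG (C^CGG, cut index = site start + 1); HpaII cuts
    only sites flagged unmethylated in ``methylome`` (no methylome = fully
    unmethylated); EcoRI cuts every GAATTC (G^AATTC). Combined reactions
    take the union of cut sets.
    """
    if enzyme not in _ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {sorted(_ENZYMES)}")
    seq = genome.record.residues
    ccgg_sites = find_sites(seq, "CCGG")
    ecori_sites = find_sites(seq, "GAATTC")
    meth_flags: dict[int, bool] = {}
    if methylome is not None:
        site_set = set(ccgg_sites)
        for pos, flag in zip(methylome.site_positions, methylome.methylated):
            if pos not in site_set:
                raise ValueError(f"methylome position {pos} is not a CCGG site of the genome")
            meth_flags[pos] = flag

    cuts: set[int] = set()
    ccgg_cuts = ecori_cuts = 0
    if "MspI" in enzyme:
        cut_sites = ccgg_sites
        cuts.update(p + 1 for p in cut_sites)
        ccgg_cuts = len(cut_sites)
    elif "HpaII" in enzyme:
        cut_sites = [p for p in ccgg_sites if not meth_flags.get(p, False)]
        cuts.update(p + 1 for p in cut_sites)
        ccgg_cuts = len(cut_sites)
    if "EcoRI" in enzyme:
        cuts.update(p + 1 for p in ecori_sites)
        ecori_cuts = len(ecori_sites)

    positions = tuple(sorted(cuts))
    L = len(seq)
    bounds = (0,) + positions + (L,)
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(
        enzyme=enzyme,
        cut_positions=positions,
        fragment_lengths=fragments,
        ccgg_cuts=ccgg_cuts,
        ecori_cuts=ecori_cuts,
    )


def virtual_gel(
    result: DigestResult,
    n_bins: int = 50,
    frag_range: tuple[float, float] = (100.0, 50_000.0),
) -> GelProfile:
    """Length-weighted fragment histogram over log-spaced size bins.

    Models an electrophoresis lane: each fragment deposits mass equal to
    its length. Fragments outside the range accumulate in the edge bins, so
    total mass always equals the genome length.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not result.fragment_lengths:
        raise ValueError("digest produced no fragments")
    lo, hi = frag_range
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    lengths = np.asarray(result.fragment_lengths, dtype=float)
    clipped = np.clip(lengths, edges[0], np.nextafter(edges[-1], 0))
    mass, _ = np.histogram(clipped, bins=edges, weights=lengths)
    return GelProfile(bin_edges=edges, mass_per_bin=mass)


def pyrogram_from_digest(result: DigestResult) -> Pyrogram:
    """Noise-free pyrosequencing peaks for a combined digestion reaction.

    Each CCGG cut contributes 2 ends x (1 C + 1 G) fill-in; each EcoRI cut
    2 ends x (2 A + 2 T). One incorporation = one light unit; totals are
    split evenly across the two dispensations carrying each label (the
    estimator sums them, so the split is observationally irrelevant). The
    H2O control peak is 0.
    """
    if result.enzyme not in ("HpaII+EcoRI", "MspI+EcoRI"):
        raise ValueError("pyrogram requires a combined CCGG-cutter + EcoRI reaction")
    gc_total = 4.0 * result.ccgg_cuts  # 2 ends x (1 C + 1 G)
    a_total = 4.0 * result.ecori_cuts  # 2 ends x 2 A
    t_total = 4.0 * result.ecori_cuts  # 2 ends x 2 T
    peaks = (
        a_total / 2,
        gc_total / 2,
        t_total / 2,
        0.0,
        gc_total / 2,
        a_total / 2,
        t_total / 2,
    )
    return Pyrogram(reaction=result.enzyme, peaks=peaks)


def luma_ratio(pyro: Pyrogram) -> float:
    """(dGTP+dCTP) / mean(dATP, dTTP) for one reaction's pyrogram."""
    p = pyro.peaks
    gc = p[1] + p[4]
    a = p[0] + p[5]
    t = p[2] + p[6]
    denom = (a + t) / 2.0
    if denom == 0:
        raise LumaError("EcoRI control failed: dATP+dTTP peak mass is zero")
    return gc / denom


def luma_percent_methylation(hpaii: Pyrogram, mspi: Pyrogram) -> LumaResult:
    """Percent methylated CCGG: 100 * [1 - (HpaII/EcoRI)/(MspI/EcoRI)]."""
    r_h = luma_ratio(hpaii)
    r_m = luma_ratio(mspi)
    if r_m == 0:
        raise LumaError("MspI/EcoRI ratio is zero: no CCGG sites detected")
    raw = 100.0 * (1.0 - r_h / r_m)
    clamped = not (0.0 <= raw <= 100.0)
    return LumaResult(
        ratio_hpaii=r_h,
        ratio_mspi=r_m,
        percent_methylation=min(max(raw, 0.0), 100.0),
        raw_percent=raw,
        clamped=clamped,
    )


def estimate_percent_methylation(
    genome: Genome,
    methylome: MethylomeTrack,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[float, list[LumaResult]]:
    """Full digest -> pyrogram -> LUMA chain, averaged over replicates.

    Replicates share the digests but receive independent multiplicative
    peak noise; percent methylation is computed per replicate and then
    averaged (mean of per-replicate percents, not of peak heights).
    """
    hpaii = pyrogram_from_digest(digest(genome, "HpaII+EcoRI", methylome))
    mspi = pyrogram_from_digest(digest(genome, "MspI+EcoRI", methylome))
    results = []
    for rep in range(n_replicates):
        if noise_cv > 0:
            h = add_pyrogram_noise(hpaii, noise_cv, seed=seed * 2_000_003 + 2 * rep)
            m = add_pyrogram_noise(mspi, noise_cv, seed=seed * 2_000_003 + 2 * rep + 1)
        else:
            h, m = hpaii, mspi
        results.append(luma_percent_methylation(h, m))
    mean_percent = float(np.mean([r.percent_methylation for r in results]))
    return mean_percent, results
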