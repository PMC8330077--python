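"""Per-CpG methylation quantification from bisulfite-converted reads.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as
T) while 5-methyl-cytosine resists conversion, so at each CpG the fraction
of reads showing C estimates the methylation level of that site. Reads here
are pre-aligned to the reference locus; non-CpG cytosines, which should be
essentially unmethylated, provide the conversion-efficiency control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import BisulfiteReadSet

__all__ = [
    "CpGMethylationProfile",
    "ReplicateSummary",
    "quantify_methylation",
    "aggregate_replicates",
    "correct_for_conversion",
]


@dataclass(frozen=True)
class CpGMethylationProfile:
    """Percent methylation and coverage per CpG of one locus/sample."""

    locus_id: str
    cpg_positions: tuple[int, ...]
    percent: tuple[float, ...]  # NaN where coverage is 0
    coverage: tuple[int, ...]  # informative (C or T) reads per CpG
    conversion_qc: float  # fraction of non-CpG reference C's read as T


@dataclass(frozen=True)
class ReplicateSummary:
    cpg_positions: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n_replicates: int


def quantify_methylation(
    readset: BisulfiteReadSet,
    qc_threshold: float = 0.95,
) -> CpGMethylationProfile:
    """Percent methylation per CpG: 100 x #C / #(C or T) at each offset.

    Residues other than C/T at a CpG (sequencing error) are excluded from
    the denominator rather than counted as unmethylated, matching
    pyrosequencing allele-quantification practice. ``conversion_qc`` is the
    T fraction among C/T calls at non-CpG reference cytosines; values below
    ``qc_threshold`` indicate failed conversion (reported, not fatal).
    """
    if len(readset.reads) == 0:
        raise ValueError("read set is empty")
    if len(readset.cpg_positions) == 0:
        raise ValueError("locus has no CpG positions to quantify")
    mat = np.frombuffer("".join(readset.reads).encode(), dtype="S1").reshape(
        len(readset.reads), readset.reference.length
    )
    cpg_idx = np.asarray(readset.cpg_positions, dtype=int)
    at_cpg = mat[:, cpg_idx]
    n_c = (at_cpg == b"C").sum(axis=0)
    n_t = (at_cpg == b"T").sum(axis=0)
    informative = n_c + n_t
    if int(informative.sum()) == 0:
        raise ValueError("zero informative (C/T) reads at every CpG")
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(informative > 0, 100.0 * n_c / informative, np.nan)

    ref = np.frombuffer(readset.reference.residues.encode(), dtype="S1")
    non_cpg_c = np.setdiff1d(np.where(ref == b"C")[0], cpg_idx)
    if len(non_cpg_c):
        ctrl = mat[:, non_cpg_c]
        c_ctrl = int((ctrl == b"C").sum())
        t_ctrl = int((ctrl == b"T").sum())
        qc = t_ctrl / (c_ctrl + t_ctrl) if (c_ctrl + t_ctrl) else float("nan")
    else:
        qc = float("nan")
    return CpGMethylationProfile(
        locus_id=readset.reference.id,
        cpg_positions=tuple(int(i) for i in cpg_idx),
        percent=tuple(float(x) for x in percent),
        coverage=tuple(int(x) for x in informative),
        conversion_qc=qc,
    )


def aggregate_replicates(profiles: list[CpGMethylationProfile]) -> ReplicateSummary:
    """Per-CpG mean and sample SD across replicate profiles of one locus."""
    if len(profiles) < 2:
        raise ValueError("replicate aggregation requires >= 2 profiles")
    positions = profiles[0].cpg_positions
    for p in profiles[1:]:
        if p.cpg_positions != positions:
            raise ValueError(
                f"replicates cover different CpG positions ({p.locus_id!r} vs {profiles[0].locus_id!r})"
            )
    arr = np.array([p.percent for p in profiles], dtype=float)
    return ReplicateSummary(
        cpg_positions=positions,
        mean=tuple(float(x) for x in arr.mean(axis=0)),
        sd=tuple(float(x) for x in arr.std(axis=0, ddof=1)),
        n_replicates=len(profiles),
    )


def correct_for_conversion(percent: float, conversion_rate: float) -> float:
    """Optional bias correction m = (p - (1-c)) / c, clamped to [0, 100].

    The raw C fraction estimates m + (1-m)(1-c) for true methylation m and
    conversion rate c; inverting removes the incomplete-conversion bias.
    Default reporting elsewhere stays uncorrected (raw percentages).
    """
    if not 0.0 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in (0, 1]")
    p = percent / 100.0
    m = (p - (1.0 - conversion_rate)) / conversion_rate
    return 100.0 * min(max(m, 0.0), 1.0)
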