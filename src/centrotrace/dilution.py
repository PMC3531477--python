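"""Closed-form dilution and ploidy arithmetic.

Covers the per-genome dilution of a conserved centromeric pool across the
two meiotic divisions, the halving of an inherited label across syncytial
cleavage cycles, the nucleocytoplasmic-ratio trigger for cellularization
in haploid versus diploid embryos, and Mendelian transmission of a
paternally carried transgene.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class EmbryoModelParams:
    diploid_cellularization_cycle: int = 13
    #: labeled fraction below which a signal counts as undetectable; the
    #: default sits strictly between the mitosis-2 fraction (0.5, seen)
    #: and the mitosis-3 fraction (0.25, not seen).
    detection_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.diploid_cellularization_cycle < 1:
            raise ValueError("diploid_cellularization_cycle must be >= 1")
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in (0, 1)")


def meiotic_dilution_factor() -> float:
    """Per-genome dilution across the two meiotic divisions.

    With no net loading during meiosis, the centromeric pool of one 4C
    spermatocyte is partitioned among four 1C spermatids: a factor of 4.
    (A naive per-spot reading would give 2 because sister centromeres stay
    paired through division I; the per-genome/per-cell factor is reported.)
    """
    return 4.0


def label_fraction_at_mitosis(k: int) -> float:
    """Labeled fraction on paternal centromeres at mitosis ``k`` (k >= 1).

    The inherited label is halved onto sisters each S phase while unlabeled
    maternal protein restores the total: (1/2)**(k-1).
    """
    if k < 1:
        raise ValueError("mitosis index must be >= 1")
    return 0.5 ** (k - 1)


def is_detectable(k: int, params: EmbryoModelParams | None = None) -> bool:
    """Whether the inherited label is still detectable at mitosis ``k``."""
    params = params or EmbryoModelParams()
    return label_fraction_at_mitosis(k) > params.detection_threshold


def cellularization_cycle(ploidy: int, params: EmbryoModelParams | None = None) -> int:
    """Syncytial cycle at which cellularization triggers.

    Cellularization occurs at the minimal cycle c with
    ``2**c * ploidy >= 2**diploid_cycle * 2``, i.e. when total genome
    content reaches the level of a diploid embryo at its normal
    cellularization cycle.  Haploids need one extra doubling.
    """
    params = params or EmbryoModelParams()
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    threshold = 2**params.diploid_cellularization_cycle * 2
    for c in range(1, 64):
        if 2**c * ploidy >= threshold:
            return c
    raise RuntimeError("no cellularization cycle found")  # pragma: no cover


def density_ratio(params: EmbryoModelParams | None = None) -> float:
    """Nuclear density at cellularization, haploid relative to diploid.

    Density is proportional to the nucleus count 2**c at the
    cellularization cycle of each ploidy.
    """
    c1 = cellularization_cycle(1, params)
    c2 = cellularization_cycle(2, params)
    return float(2**c1) / float(2**c2)


def mendelian_transmission_fraction(father: str) -> float:
    """Expected fraction of progeny inheriting a paternal transgene."""
    fractions = {"hemizygous": 0.5, "homozygous": 1.0}
    if father not in fractions:
        raise ValueError("father must be 'hemizygous' or 'homozygous'")
    return fractions[father]


def transmission_excess_pvalue(n_positive: int, n_total: int, p: float = 0.5) -> float:
    """One-sided binomial tail P(X >= n_positive) under transmission p.

    Used to test whether an observed positive fraction exceeds the
    Mendelian expectation (which would rule out zygotic expression as the
    source of the observed signal).
    """
    return float(stats.binomtest(n_positive, n_total, p, alternative="greater").pvalue)
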