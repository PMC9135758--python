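"""Allele-specific genotype states and their emission expectations.

The joint CNV/LOH model describes each locus by a genotype state ``(c, a)``:
total copy number ``c`` and the number of copies of the *reference* allele
``a`` at a germline-heterozygous site (germline genotype is one reference of
two copies).  Each pair maps to exactly one LOH-type label and one CNV-class
label:

====  ===  =========  =========
c     a    loh_label  cnv_label
====  ===  =========  =========
1     0,1  DLOH       HEMD
2     1    HET        NEUT
2     0,2  NLOH       NEUT
3     1,2  GAIN       AMP
3     0,3  ALOH       AMP
4     2    BCNA       AMP
4     1,3  UBCNA      AMP
4     0,4  ALOH       AMP
====  ===  =========  =========

On the amplification-specific track the allele-specific gains (3,1)/(3,2) are
conventionally called ASCNA; that synonym is exposed as ``amp_label``.

Emission expectations mix three cell populations: normal cells (fraction
``n``, diploid heterozygous), tumor cells carrying the event (tumor fraction
``s``, the subclone's cellular prevalence) and tumor cells without it.  With
the aberrant-cell fraction ``phi = (1 - n) * s``::

    mean copies        cbar = 2*n + (1-n)*(s*c + (1-s)*2) = 2 + phi*(c - 2)
    expected log-ratio      = log2(cbar / 2)
    expected ref fraction   = [n + (1-n)*(s*a + (1-s))] / cbar
                            = (1 + phi*(a - 1)) / cbar

Both expectations depend on ``(n, s)`` only through ``phi``; see
``docs/methods.md`` for how the fitted model decomposes ``phi`` back into a
normal fraction and per-cluster prevalences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

LOH_CATALOG: dict[tuple[int, int], str] = {
    (1, 0): "DLOH", (1, 1): "DLOH",
    (2, 0): "NLOH", (2, 1): "HET", (2, 2): "NLOH",
    (3, 0): "ALOH", (3, 1): "GAIN", (3, 2): "GAIN", (3, 3): "ALOH",
    (4, 0): "ALOH", (4, 1): "UBCNA", (4, 2): "BCNA", (4, 3): "UBCNA", (4, 4): "ALOH",
}

AMP_LABELS: dict[tuple[int, int], str] = {
    (3, 1): "ASCNA", (3, 2): "ASCNA",
    (4, 1): "UBCNA", (4, 3): "UBCNA", (4, 2): "BCNA",
}


@dataclass(frozen=True)
class GenotypeState:
    """A (total copies, reference-allele copies) pair with its labels."""

    c: int
    a: int

    def __post_init__(self) -> None:
        if (self.c, self.a) not in LOH_CATALOG:
            raise ValueError(f"no genotype state for (c={self.c}, a={self.a})")

    @property
    def loh_label(self) -> str:
        return LOH_CATALOG[(self.c, self.a)]

    @property
    def cnv_label(self) -> str:
        if self.c < 2:
            return "HEMD"
        if self.c == 2:
            return "NEUT"
        return "AMP"

    @property
    def amp_label(self) -> str | None:
        """Amplification-track synonym (ASCNA/BCNA/UBCNA); None below 3 copies."""
        return AMP_LABELS.get((self.c, self.a))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.c},{self.a}):{self.loh_label}/{self.cnv_label}"


def enumerate_states(c_max: int = 4) -> list[GenotypeState]:
    """All genotype states with ``1 <= c <= c_max``, ordered by ``(c, a)``.

    ``c_max`` must be between 2 and 4 (the catalog covers up to 4 copies).
    """
    if not 2 <= c_max <= 4:
        raise ValueError("c_max must be in [2, 4]")
    return [GenotypeState(c, a) for c in range(1, c_max + 1) for a in range(c + 1)]


HET_STATE = GenotypeState(2, 1)


def _check_sn(s: float, n: float) -> None:
    if not 0.0 < s <= 1.0:
        raise ValueError(f"prevalence s must be in (0, 1], got {s}")
    if not 0.0 <= n < 1.0:
        raise ValueError(f"normal fraction n must be in [0, 1), got {n}")


def aberrant_fraction(s: float, n: float) -> float:
    """Fraction of all cells carrying the event: phi = (1 - n) * s."""
    _check_sn(s, n)
    return (1.0 - n) * s


def logratio_from_phi(c: float, phi: float) -> float:
    return math.log2((2.0 + phi * (c - 2.0)) / 2.0)


def reffraction_from_phi(c: float, a: float, phi: float) -> float:
    return (1.0 + phi * (a - 1.0)) / (2.0 + phi * (c - 2.0))


def expected_logratio(state: GenotypeState, s: float, n: float) -> float:
    """Expected log2 depth ratio of a locus in genotype ``state``.

    ``s`` is the carrier subclone's cellular prevalence (fraction of tumor
    cells), ``n`` the normal-cell contamination of the sample.
    """
    return logratio_from_phi(state.c, aberrant_fraction(s, n))


def expected_reffraction(state: GenotypeState, s: float, n: float) -> float:
    """Expected fraction of reads matching the reference allele at a het site."""
    return reffraction_from_phi(state.c, state.a, aberrant_fraction(s, n))
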