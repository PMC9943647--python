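"""Three-site equilibrium binding polynomial.

A DNA molecule carrying three protein binding sites partitions, at free-ligand
concentration ``L``, among four ligation states (0, 1, 2 or 3 proteins bound).
The population of each state follows from the binding polynomial

    Z = 1 + K1*L + K2*L**2 + K3*L**3

whose coefficients K1..K3 (macroscopic association constants, units of
uM^-1, uM^-2, uM^-3) are sums of microscopic per-site constants k1, k2, k3
and pairwise cooperativity factors k12, k13, k23:

    K1 = k1 + k2 + k3
    K2 = k1*k2*k12 + k1*k3*k13 + k2*k3*k23
    K3 = k1*k2*k3 * (k12 + k13 + k23)        (default "sum" convention)

Note the sum in the triply-liganded coefficient: under this convention the
identical-independent-site limit (all k equal to Ka, all couplings 1) gives
Z = 1 + 3*Ka*L + 3*Ka**2*L**2 + 3*Ka**3*L**3 rather than the binomial
(1 + Ka*L)**3.  The alternative product convention
K3 = k1*k2*k3*k12*k13*k23 is available through ``triple_term="product"``.

Cooperativity of the second and third binding events is judged from the ratio
statistics r2 = 3*K2/K1**2 and r3 = 3*K3/(K1*K2); a ratio above 1 indicates a
cooperative event.  When binding is independent and the three sites are
identical, the macroscopic constants reduce to K1 = 3*Ka, K2 = 3*Ka**2,
K3 = 3*Ka**3, which lets a single per-site association constant Ka (and its
reciprocal dissociation constant Kd) be read back from a fitted (K1, K2, K3).

All concentrations are in uM throughout the package; constants carry the
matching reciprocal powers and are never auto-converted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

__all__ = [
    "MicroscopicConstants",
    "MacroscopicConstants",
    "SpeciesFractions",
    "CooperativityRatios",
    "UndefinedRatioError",
    "species_fractions",
    "macro_from_micro",
    "microstate_oracle",
    "cooperativity_ratios",
    "ka_from_macro",
]


class UndefinedRatioError(ValueError):
    """A cooperativity ratio whose denominator is zero was requested."""

    def __init__(self, which: str) -> None:
        self.which = which
        super().__init__(
            f"cooperativity ratio {which} is undefined: its denominator is zero"
        )


@dataclass(frozen=True)
class MicroscopicConstants:
    """Per-site intrinsic constants (uM^-1) and pairwise coupling factors.

    ``k12 = k13 = k23 = 1`` with ``k1 = k2 = k3`` encodes identical
    independent sites.
    """

    k1: float
    k2: float
    k3: float
    k12: float = 1.0
    k13: float = 1.0
    k23: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k12", "k13", "k23"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def identical_independent(cls, ka: float) -> "MicroscopicConstants":
        return cls(ka, ka, ka, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class MacroscopicConstants:
    """Coefficients of the binding polynomial: K1 (uM^-1), K2 (uM^-2), K3 (uM^-3)."""

    K1: float
    K2: float
    K3: float

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "K3"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def __iter__(self):
        return iter((self.K1, self.K2, self.K3))

    def polynomial(self, L: float) -> float:
        """Binding polynomial Z(L) = 1 + K1*L + K2*L^2 + K3*L^3."""
        return 1.0 + self.K1 * L + self.K2 * L**2 + self.K3 * L**3

    @classmethod
    def from_site_ka(cls, ka: float) -> "MacroscopicConstants":
        """Identical-independent-site construction K = (3Ka, 3Ka^2, 3Ka^3)."""
        if ka <= 0:
            raise ValueError(f"ka must be > 0, got {ka}")
        return cls(3.0 * ka, 3.0 * ka**2, 3.0 * ka**3)


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of DNA with exactly 0..3 ligands bound at free ligand L (uM)."""

    theta0: float
    theta1: float
    theta2: float
    theta3: float
    L: float
    Z: float

    def __iter__(self):
        return iter((self.theta0, self.theta1, self.theta2, self.theta3))

    @property
    def bound_sites_per_dna(self) -> float:
        """Mean number of occupied sites, theta1 + 2*theta2 + 3*theta3."""
        return self.theta1 + 2.0 * self.theta2 + 3.0 * self.theta3


def species_fractions(L: float, K: MacroscopicConstants) -> SpeciesFractions:
    """Ligation-state fractions at free ligand concentration ``L`` (uM).

    theta_i = K_i * L^i / Z with K_0 = 1 and Z = 1 + K1*L + K2*L^2 + K3*L^3.
    """
    if not math.isfinite(L) or L < 0:
        raise ValueError(f"free ligand concentration must be finite and >= 0, got {L}")
    # Normalize by the largest term so Z stays representable at extreme L.
    terms = [1.0, K.K1 * L, K.K2 * L**2, K.K3 * L**3]
    m = max(terms)
    z_scaled = sum(t / m for t in terms)
    thetas = [t / m / z_scaled for t in terms]
    return SpeciesFractions(*thetas, L=L, Z=m * z_scaled)


def macro_from_micro(
    m: MicroscopicConstants, *, triple_term: str = "sum"
) -> MacroscopicConstants:
    """Collapse microscopic constants into the macroscopic (K1, K2, K3).

    ``triple_term`` selects the convention for the triply-liganded coefficient:
    ``"sum"`` (default) uses k1*k2*k3*(k12 + k13 + k23); ``"product"`` uses
    k1*k2*k3*k12*k13*k23.
    """
    K1 = m.k1 + m.k2 + m.k3
    K2 = m.k1 * m.k2 * m.k12 + m.k1 * m.k3 * m.k13 + m.k2 * m.k3 * m.k23
    if triple_term == "sum":
        K3 = m.k1 * m.k2 * m.k3 * (m.k12 + m.k13 + m.k23)
    elif triple_term == "product":
        K3 = m.k1 * m.k2 * m.k3 * m.k12 * m.k13 * m.k23
    else:
        raise ValueError(f"triple_term must be 'sum' or 'product', got {triple_term!r}")
    return MacroscopicConstants(K1, K2, K3)


#: statistical weight of each ligation configuration, by occupied-site subset
_PAIRS = {frozenset({1, 2}): "k12", frozenset({1, 3}): "k13", frozenset({2, 3}): "k23"}


def microstate_oracle(
    m: MicroscopicConstants, L: float, *, triple_term: str = "sum"
) -> SpeciesFractions:
    """Ligation-state fractions by explicit enumeration of the 8 configurations.

    Weights: empty site set -> 1; single site i -> ki*L; pair {i,j} ->
    ki*kj*kij*L^2; all three -> k1*k2*k3*(k12+k13+k23)*L^3 under the default
    sum convention (product of all three couplings under ``"product"``).
    Serves as an independent check on :func:`species_fractions` composed with
    :func:`macro_from_micro`.
    """
    if not math.isfinite(L) or L < 0:
        raise ValueError(f"free ligand concentration must be finite and >= 0, got {L}")
    site_k = {1: m.k1, 2: m.k2, 3: m.k3}
    weights = [0.0, 0.0, 0.0, 0.0]
    for r in range(4):
        for subset in itertools.combinations((1, 2, 3), r):
            w = L**r
            for i in subset:
                w *= site_k[i]
            if r == 2:
                w *= getattr(m, _PAIRS[frozenset(subset)])
            elif r == 3:
                if triple_term == "sum":
                    w *= m.k12 + m.k13 + m.k23
                elif triple_term == "product":
                    w *= m.k12 * m.k13 * m.k23
                else:
                    raise ValueError(
                        f"triple_term must be 'sum' or 'product', got {triple_term!r}"
                    )
            weights[r] += w
    Z = sum(weights)
    return SpeciesFractions(*(w / Z for w in weights), L=L, Z=Z)


@dataclass(frozen=True)
class CooperativityRatios:
    """Ratio statistics for the second and third binding events.

    r2 = K2 / (K1^2 / 3) and r3 = K3 / (K1*K2 / 3); a value above 1 marks the
    corresponding event as cooperative.  Accessing a ratio whose denominator
    vanished raises :class:`UndefinedRatioError`.
    """

    _r2: float | None = field(repr=False)
    _r3: float | None = field(repr=False)

    @property
    def r2(self) -> float:
        if self._r2 is None:
            raise UndefinedRatioError("r2")
        return self._r2

    @property
    def r3(self) -> float:
        if self._r3 is None:
            raise UndefinedRatioError("r3")
        return self._r3

    def __iter__(self):
        return iter((self.r2, self.r3))


def cooperativity_ratios(K: MacroscopicConstants) -> CooperativityRatios:
    """Compute (r2, r3) = (3*K2/K1**2, 3*K3/(K1*K2))."""
    r2 = 3.0 * K.K2 / K.K1**2 if K.K1 > 0 else None
    r3 = 3.0 * K.K3 / (K.K1 * K.K2) if K.K1 * K.K2 > 0 else None
    return CooperativityRatios(r2, r3)


@dataclass(frozen=True)
class SiteAffinity:
    """Per-site Ka read back from macroscopic constants under independence."""

    estimates: tuple[float, float, float]
    Ka: float  # uM^-1, arithmetic mean of the three per-order estimates
    Kd: float  # uM, 1/Ka


def ka_from_macro(K: MacroscopicConstants) -> SiteAffinity:
    """Reduce (K1, K2, K3) to a per-site Ka assuming identical independent sites.

    Inverts K1 = 3Ka, K2 = 3Ka^2, K3 = 3Ka^3 order by order, giving the three
    estimates (K1/3, sqrt(K2/3), cbrt(K3/3)); Ka is their arithmetic mean and
    Kd = 1/Ka.  Only meaningful when no cooperativity was inferred.
    """
    if not (K.K1 > 0 and K.K2 > 0 and K.K3 > 0):
        raise ValueError(
            "identical-site reduction requires K1, K2, K3 > 0, got "
            f"({K.K1}, {K.K2}, {K.K3})"
        )
    estimates = (K.K1 / 3.0, math.sqrt(K.K2 / 3.0), (K.K3 / 3.0) ** (1.0 / 3.0))
    ka = sum(estimates) / 3.0
    return SiteAffinity(estimates=estimates, Ka=ka, Kd=1.0 / ka)
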