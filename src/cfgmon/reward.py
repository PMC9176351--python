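"""The generator's reward: r(I) = F(I) * G(I).

``F`` rewards long absorption wavelength and ``G`` rewards ease of
synthesis; both are tanh sigmoids mapped into (0, 1):

    F(I) = (tanh(slope * (lambda_I - theta)) + 1) / 2
    G(I) = (-tanh(SA_I - sa_center) + 1) / 2

with defaults slope = 0.003 / nm, theta = 400 nm (so F = 0.5 exactly at
400 nm) and sa_center = 4 on the conventional 1 (easy) to 10 (hard)
synthetic-accessibility scale.

Wavelength and SA providers are injection points. The default
wavelength provider is a deliberately simple structural surrogate,

    lambda_hat = a + b * conjugate_length + c * aromatic_ring_count

(a = 150 nm, b = 25 nm/atom, c = 20 nm/ring), standing in for an
electronic-structure calculation: it preserves the qualitative fact
that extending conjugation and adding aromatic rings red-shifts the
absorption, which is all the search needs to exhibit learning. The
default SA provider is the Ertl–Schuffenhauer fragment-contribution
score bundled with RDKit; a purely structural proxy
(1 + 0.3 * rings + 0.05 * heavy atoms, capped at 10) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .catalog import MoleculeRecord
from .properties import aromatic_ring_count, conjugate_length

__all__ = [
    "RewardParams",
    "RewardBreakdown",
    "SurrogateLambdaCoeffs",
    "wavelength_term",
    "sa_term",
    "reward",
    "surrogate_lambda",
    "sa_score",
    "proxy_sa_score",
    "ertl_sa_score",
    "default_reward_fn",
]


@dataclass(frozen=True)
class RewardParams:
    """Shape parameters of the two reward sigmoids."""

    theta: float = 400.0  # comparative wavelength criterion, nm
    slope: float = 0.003  # wavelength sigmoid slope, 1/nm
    sa_center: float = 4.0  # SA pivot where G = 0.5

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")


@dataclass(frozen=True)
class RewardBreakdown:
    """All intermediate quantities of one reward evaluation."""

    lambda_value: float
    sa_value: float
    f: float
    g: float
    r: float


@dataclass(frozen=True)
class SurrogateLambdaCoeffs:
    """Affine coefficients of the structural wavelength surrogate."""

    intercept: float = 150.0  # nm
    per_conjugated_atom: float = 25.0  # nm/atom
    per_aromatic_ring: float = 20.0  # nm/ring


def wavelength_term(lambda_nm: float, params: RewardParams = RewardParams()) -> float:
    """F(I): strictly increasing in lambda, equal to 0.5 at theta."""
    if lambda_nm < 0:
        raise ValueError("wavelength must be non-negative")
    return (math.tanh(params.slope * (lambda_nm - params.theta)) + 1.0) / 2.0


def sa_term(sa: float, params: RewardParams = RewardParams()) -> float:
    """G(I): strictly decreasing in the SA score, equal to 0.5 at the pivot."""
    return (-math.tanh(sa - params.sa_center) + 1.0) / 2.0


def surrogate_lambda(
    molecule: MoleculeRecord | Chem.Mol,
    coeffs: SurrogateLambdaCoeffs = SurrogateLambdaCoeffs(),
) -> float:
    """Deterministic structural stand-in for a computed absorption wavelength."""
    return (
        coeffs.intercept
        + coeffs.per_conjugated_atom * conjugate_length(molecule)
        + coeffs.per_aromatic_ring * aromatic_ring_count(molecule)
    )


def proxy_sa_score(molecule: MoleculeRecord | Chem.Mol) -> float:
    """Structural SA proxy: 1 + 0.3 * rings + 0.05 * heavy atoms, capped at 10."""
    mol = molecule.mol if isinstance(molecule, MoleculeRecord) else molecule
    if mol is None:
        raise ValueError("invalid molecule")
    n_rings = rdMolDescriptors.CalcNumRings(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    return min(10.0, 1.0 + 0.3 * n_rings + 0.05 * n_heavy)


def _load_ertl() -> Callable[[Chem.Mol], float] | None:
    try:  # bundled with RDKit under Contrib, not on the import path by default
        import os
        import sys

        from rdkit.Chem import RDConfig

        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # type: ignore[import-not-found]

        return sascorer.calculateScore
    except Exception:
        return None


_ERTL = _load_ertl()


def ertl_sa_score(molecule: MoleculeRecord | Chem.Mol) -> float:
    """Ertl–Schuffenhauer fragment-contribution SA score (1 easy .. 10 hard)."""
    if _ERTL is None:
        raise RuntimeError("Ertl SA scorer not available in this RDKit build")
    mol = molecule.mol if isinstance(molecule, MoleculeRecord) else molecule
    if mol is None:
        raise ValueError("invalid molecule")
    return float(_ERTL(mol))


def sa_score(molecule: MoleculeRecord | Chem.Mol, provider: str = "auto") -> float:
    """SA score from the configured provider.

    ``"auto"`` prefers the Ertl scorer and falls back to the structural
    proxy; ``"ertl"`` and ``"proxy"`` force one or the other.
    """
    if provider == "auto":
        return ertl_sa_score(molecule) if _ERTL is not None else proxy_sa_score(molecule)
    if provider == "ertl":
        return ertl_sa_score(molecule)
    if provider == "proxy":
        return proxy_sa_score(molecule)
    raise ValueError(f"unknown SA provider {provider!r}")


def reward(
    molecule: MoleculeRecord | Chem.Mol,
    lambda_provider: Callable[[Chem.Mol], float] = surrogate_lambda,
    sa_provider: Callable[[Chem.Mol], float] = sa_score,
    params: RewardParams = RewardParams(),
) -> RewardBreakdown:
    """Full reward breakdown r = F * G for one molecule.

    Invalid records get the zero-reward convention (r = 0 with NaN
    components) so a search can always rank its rollouts.
    """
    if isinstance(molecule, MoleculeRecord) and (not molecule.valid or molecule.mol is None):
        return RewardBreakdown(
            lambda_value=math.nan, sa_value=math.nan, f=0.0, g=0.0, r=0.0
        )
    mol = molecule.mol if isinstance(molecule, MoleculeRecord) else molecule
    try:
        lam = float(lambda_provider(mol))
        sa = float(sa_provider(mol))
    except Exception as exc:
        index = molecule.index if isinstance(molecule, MoleculeRecord) else "?"
        raise RuntimeError(f"reward provider failed for molecule {index}: {exc}") from exc
    f = wavelength_term(lam, params)
    g = sa_term(sa, params)
    return RewardBreakdown(lambda_value=lam, sa_value=sa, f=f, g=g, r=f * g)


def default_reward_fn(
    params: RewardParams = RewardParams(),
    coeffs: SurrogateLambdaCoeffs = SurrogateLambdaCoeffs(),
    sa_provider_name: str = "auto",
) -> Callable[[Chem.Mol], RewardBreakdown]:
    """Reward closure over the surrogate wavelength and configured SA provider."""

    def fn(mol: Chem.Mol) -> RewardBreakdown:
        return reward(
            mol,
            lambda_provider=lambda m: surrogate_lambda(m, coeffs),
            sa_provider=lambda m: sa_score(m, sa_provider_name),
            params=params,
        )

    return fn
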