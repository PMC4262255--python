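"""Pedigree-based imputation of marker covariates for non-genotyped animals.

Observed allele dosages M2 (rows = genotyped "set 2" animals) are extended to
the non-genotyped "set 1" by best linear prediction given the pedigree:
M1_hat = A_12 A_22^{-1} M2, computed without any dense inverse by solving the
very sparse system A^{11} M1_hat = -A^{12} M2 column by column, where A^{ij}
are blocks of the pedigree A-inverse. The companion covariate J (J2 = -1 for
genotyped animals, A^{11} J1 = -A^{12} J2 for the rest) carries the fixed
effect mu_g that replaces explicit centering when founder allele frequencies
are unknown. The deviation of each set-1 animal's true breeding value from
its imputed prediction is the "imputation residual" epsilon, whose precision
matrix is A^{11} (up to 1/sigma^2_eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import RelationshipSystem

__all__ = [
    "MarkerData",
    "ImputedCovariates",
    "impute_markers",
    "compute_J",
    "center_markers",
    "var_alpha_from_var_g",
]


@dataclass
class MarkerData:
    """Observed dosage matrix for the genotyped set.

    ``M2`` holds allele dosages (0/1/2 before centering), one row per set-2
    individual in genotype-file order. ``centering`` is None for raw coding
    or the per-marker offset k' that has been subtracted.
    """

    marker_ids: list[str]
    M2: np.ndarray
    centering: np.ndarray | None = None

    def __post_init__(self):
        self.M2 = np.asarray(self.M2, dtype=float)
        if self.M2.ndim != 2:
            raise ValueError("M2 must be 2-dimensional")
        if self.M2.shape[1] != len(self.marker_ids):
            raise ValueError(
                f"M2 has {self.M2.shape[1]} columns for {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids are not unique")
        if self.centering is None and self.M2.size:
            if not np.isin(self.M2, (0.0, 1.0, 2.0)).all():
                raise ValueError("uncentered dosages must be coded 0/1/2")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def observed_freqs(self) -> np.ndarray:
        """Allele frequencies observed in set 2 (dosage mean / 2)."""
        raw = self.M2 if self.centering is None else self.M2 + self.centering
        return raw.mean(axis=0) / 2.0


@dataclass
class ImputedCovariates:
    """Imputed covariates M1_hat and the mu_g covariate J for both sets."""

    M1_hat: np.ndarray
    J1: np.ndarray
    J2: np.ndarray
    rel: RelationshipSystem = field(repr=False)

    @property
    def eps_precision(self):
        """Sparse A^{11}: precision of the imputation residual up to 1/sigma^2_eps."""
        return self.rel.A11


def impute_markers(rel: RelationshipSystem, md: MarkerData) -> ImputedCovariates:
    """Impute set-1 marker covariates and the J covariates by sparse solves.

    A^{11} is factorized once (cached on ``rel``) and reused for all marker
    columns and for J1. The result equals the dense best linear predictor
    A_12 A_22^{-1} M2 but never forms A or any inverse.
    """
    if md.M2.shape[0] != rel.n2:
        raise ValueError(
            f"genotype rows ({md.M2.shape[0]}) do not match genotyped set ({rel.n2})"
        )
    if rel.n1 == 0:
        M1_hat = np.zeros((0, md.n_markers))
        J1 = np.zeros(0)
    else:
        rhs = -rel.A12 @ md.M2 if rel.n2 else np.zeros((rel.n1, md.n_markers))
        M1_hat = np.atleast_2d(rel.solve_A11(rhs))
        if M1_hat.shape != (rel.n1, md.n_markers):
            M1_hat = M1_hat.reshape(rel.n1, md.n_markers)
        J1 = _solve_J1(rel)
    J2 = -np.ones(rel.n2)
    return ImputedCovariates(M1_hat=M1_hat, J1=J1, J2=J2, rel=rel)


def _solve_J1(rel: RelationshipSystem) -> np.ndarray:
    J2 = -np.ones(rel.n2)
    if rel.n2 == 0:
        return np.zeros(rel.n1)
    rhs = -(rel.A12 @ J2)
    return np.asarray(rel.solve_A11(rhs)).ravel()


def compute_J(rel: RelationshipSystem) -> tuple[np.ndarray, np.ndarray]:
    """The mu_g covariate: J2 = -1 over set 2; A^{11} J1 = -A^{12} J2."""
    J1 = _solve_J1(rel) if rel.n1 else np.zeros(0)
    return J1, -np.ones(rel.n2)


def center_markers(md: MarkerData, k_prime="observed-mean") -> MarkerData:
    """Return a copy of ``md`` with covariates centered by k'.

    ``k_prime`` may be a per-marker vector of expected dosages or the string
    "observed-mean" (column means of M2, i.e. twice the observed allele
    frequency). A zero vector is a no-op and keeps centering = None.
    """
    raw = md.M2 if md.centering is None else md.M2 + md.centering
    if isinstance(k_prime, str):
        if k_prime != "observed-mean":
            raise ValueError(f"unknown centering rule {k_prime!r}")
        k = raw.mean(axis=0)
    else:
        k = np.asarray(k_prime, dtype=float)
        if k.shape != (md.n_markers,):
            raise ValueError("k_prime length does not match marker count")
    if not np.any(k):
        return MarkerData(md.marker_ids, raw, centering=None)
    return MarkerData(md.marker_ids, raw - k, centering=k)


def var_alpha_from_var_g(sigma2_g: float, freqs: np.ndarray) -> float:
    """Convert a genetic variance to a per-marker effect variance.

    sigma^2_alpha = sigma^2_g / sum_j 2 p_j (1 - p_j), the standard scaling
    that makes the marker-generated genetic variance match sigma^2_g under
    linkage equilibrium.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if denom <= 0:
        raise ValueError("sum of 2pq is zero; cannot scale marker variance")
    return float(sigma2_g) / denom
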