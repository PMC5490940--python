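"""Ligand-set similarity of proteins with extreme-value calibration (SEA).

Two proteins are compared through the aggregate chemical similarity of
their ligand sets: the *raw score* sums the Tanimoto coefficient (Tc) of
every cross-pair of ligand fingerprints whose Tc exceeds a cutoff
(default 0.55). Raw scores grow with set sizes, so they are standardized
against a random background: the background mean and SD of the raw score
are fitted as smooth functions of the set-size product n1*n2, giving a
Z-score per comparison. Background Z-scores of set-similarity statistics
are right-skewed and are better described by an extreme-value (Gumbel)
distribution than by a Gaussian; a Gumbel fit (mu, sigma) converts a
Z-score into a per-comparison tail probability and, multiplied by the
number of comparisons performed, into an E-value. Pairs with
E <= 1e-4 are called significantly similar.

Fingerprints are plain fixed-length bitsets (numpy bool arrays). The
default molecule backend is a deterministic hashed-substring fingerprint,
so no chemistry toolkit is needed; a Morgan backend via RDKit is available
when installed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import gumbel_r, norm

__all__ = [
    "FingerprintSet",
    "tanimoto",
    "tanimoto_matrix",
    "raw_score",
    "SeaCalibration",
    "fit_background",
    "z_score",
    "EvdFit",
    "fit_evd",
    "calibrate_evd",
    "e_value",
    "hashed_fingerprint",
    "fingerprint_molecules",
]

TC_CUTOFF = 0.55
E_VALUE_CUTOFF = 1e-4


@dataclass
class FingerprintSet:
    """A protein's ligands as a (n_ligands, n_bits) boolean fingerprint array."""

    protein_id: str
    fingerprints: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprints, dtype=bool)
        if fp.ndim != 2 or fp.shape[0] == 0:
            raise ValueError("fingerprints must be a non-empty 2-D bit array")
        self.fingerprints = fp

    def __len__(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a & b| / |a | b| of two equal-length bitsets.

    Defined as 0 when both bitsets are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"bitset length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All cross-pair Tanimoto coefficients of two fingerprint arrays."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint lengths differ")
    ai = A.astype(np.float64)
    bi = B.astype(np.float64)
    inter = ai @ bi.T
    union = ai.sum(axis=1)[:, None] + bi.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / union, 0.0)
    return tc


def raw_score(
    A: FingerprintSet | np.ndarray,
    B: FingerprintSet | np.ndarray,
    cutoff: float = TC_CUTOFF,
) -> float:
    """Sum of cross-pair Tanimoto coefficients strictly above the cutoff.

    Symmetric, non-negative, and monotone non-decreasing when a ligand is
    added to either set.
    """
    fa = A.fingerprints if isinstance(A, FingerprintSet) else np.asarray(A, dtype=bool)
    fb = B.fingerprints if isinstance(B, FingerprintSet) else np.asarray(B, dtype=bool)
    tc = tanimoto_matrix(fa, fb)
    return float(tc[tc > cutoff].sum())


@dataclass
class SeaCalibration:
    """Size-dependent background fits plus extreme-value parameters.

    ``mean_coef`` are the coefficients of a linear fit of the background
    raw-score mean against the set-size product P = n1*n2 (the mean of a
    sum of i.i.d. per-pair contributions is exactly linear in P). The SD
    is fitted linearly in P as well (``sd_form='linear'``); a log-log
    power-law fit (``sd_form='powerlaw'``) is available for backgrounds
    where the shared-ligand covariance term makes the SD grow visibly
    faster than linearly over the sampled size range. ``n_comparisons``
    scales per-comparison tail probabilities into E-values.
    """

    tc_cutoff: float = TC_CUTOFF
    mean_coef: tuple[float, float] = (0.0, 0.0)  # (slope, intercept) in P
    sd_coef: tuple[float, float] = (0.0, 0.0)
    sd_form: str = "linear"
    evd_mu: float | None = None
    evd_sigma: float | None = None
    n_comparisons: int = 1

    def mean_at(self, product: float) -> float:
        s, i = self.mean_coef
        return s * product + i

    def sd_at(self, product: float) -> float:
        s, i = self.sd_coef
        if self.sd_form == "powerlaw":
            return float(np.exp(i) * product**s)
        return s * product + i

    # --- JSON round trip ---------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tc_cutoff": self.tc_cutoff,
                    "mean_coef": list(self.mean_coef),
                    "sd_coef": list(self.sd_coef),
                    "sd_form": self.sd_form,
                    "evd_mu": self.evd_mu,
                    "evd_sigma": self.evd_sigma,
                    "n_comparisons": self.n_comparisons,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SeaCalibration":
        with open(path) as fh:
            d = json.load(fh)
        d["mean_coef"] = tuple(d["mean_coef"])
        d["sd_coef"] = tuple(d["sd_coef"])
        return cls(**d)


def fit_background(
    draw_set: Callable[[int, np.random.Generator], np.ndarray],
    size_grid: Sequence[tuple[int, int]],
    n_samples_per_cell: int = 100,
    cutoff: float = TC_CUTOFF,
    rng_seed: int | np.random.Generator = 0,
    sd_form: str = "linear",
    n_comparisons: int = 1,
) -> SeaCalibration:
    """Fit the size-dependent raw-score background from random ligand sets.

    Parameters
    ----------
    draw_set : callable
        ``draw_set(n, rng)`` returning a (n, n_bits) boolean fingerprint
        array of n random ligands (e.g. the synthetic scaffold sampler, or
        a sampler over a real compound library).
    size_grid : sequence of (n1, n2)
        Set-size cells at which the background is sampled; at least two
        distinct products n1*n2 are required.
    n_samples_per_cell : int
        Random set pairs per cell (>= 30).

    Returns a :class:`SeaCalibration` with mean and SD fitted against the
    size product by least squares. A degenerate (constant) background
    raises a ValueError.
    """
    products = sorted({n1 * n2 for n1, n2 in size_grid})
    if len(products) < 2:
        raise ValueError("need at least 2 distinct size products in the grid")
    if n_samples_per_cell < 30:
        raise ValueError("need at least 30 samples per size cell")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    Ps, means, sds = [], [], []
    all_scores = []
    for n1, n2 in size_grid:
        scores = np.empty(n_samples_per_cell)
        for i in range(n_samples_per_cell):
            scores[i] = raw_score(draw_set(n1, rng), draw_set(n2, rng), cutoff)
        Ps.append(n1 * n2)
        means.append(scores.mean())
        sds.append(scores.std(ddof=1))
        all_scores.append(scores)
    Ps = np.array(Ps, dtype=float)
    means = np.array(means)
    sds = np.array(sds)
    if np.ptp(np.concatenate(all_scores)) == 0:
        raise ValueError("degenerate background: all raw scores identical")
    if (sds <= 0).any():
        raise ValueError("degenerate background: zero SD in a size cell")

    mean_coef = tuple(np.polyfit(Ps, means, 1))
    if sd_form == "powerlaw":
        sd_coef = tuple(np.polyfit(np.log(Ps), np.log(sds), 1))
    elif sd_form == "linear":
        sd_coef = tuple(np.polyfit(Ps, sds, 1))
    else:
        raise ValueError(f"unknown sd_form {sd_form!r}")
    cal = SeaCalibration(
        tc_cutoff=cutoff,
        mean_coef=mean_coef,
        sd_coef=sd_coef,
        sd_form=sd_form,
        n_comparisons=n_comparisons,
    )
    # sanity: fitted SD must stay positive across the sampled range
    for P in Ps:
        if cal.sd_at(P) <= 0:
            raise ValueError("fitted SD non-positive at sampled sizes")
    return cal


def z_score(raw: float, n1: int, n2: int, cal: SeaCalibration) -> float:
    """Standardize a raw score against the size-dependent background."""
    P = n1 * n2
    sd = cal.sd_at(P)
    if sd <= 0:
        raise ValueError(f"fitted background SD is non-positive at size product {P}")
    return float((raw - cal.mean_at(P)) / sd)


@dataclass
class EvdFit:
    mu: float
    sigma: float
    loglik_gumbel: float
    loglik_gaussian: float

    @property
    def prefers_gumbel(self) -> bool:
        return self.loglik_gumbel > self.loglik_gaussian


def fit_evd(z_samples: np.ndarray) -> EvdFit:
    """Maximum-likelihood Gumbel fit of background Z-scores vs a Gaussian.

    Returns the Gumbel location/scale and the total log-likelihood of both
    fits; on right-skewed set-similarity backgrounds the Gumbel wins.
    """
    z = np.asarray(z_samples, dtype=float)
    if len(z) < 1000:
        raise ValueError("need at least 1000 samples for a stable EVD fit")
    if not np.isfinite(z).all():
        raise ValueError("non-finite z samples")
    mu, sigma = gumbel_r.fit(z)
    ll_g = float(gumbel_r.logpdf(z, mu, sigma).sum())
    m, s = norm.fit(z)
    ll_n = float(norm.logpdf(z, m, s).sum())
    return EvdFit(mu=float(mu), sigma=float(sigma), loglik_gumbel=ll_g, loglik_gaussian=ll_n)


def calibrate_evd(cal: SeaCalibration, z_samples: np.ndarray) -> EvdFit:
    """Fit the EVD on background Z-scores and store it in the calibration."""
    fit = fit_evd(z_samples)
    cal.evd_mu = fit.mu
    cal.evd_sigma = fit.sigma
    return fit


def e_value(z: float, cal: SeaCalibration) -> float:
    """Expected number of comparisons scoring at least z by chance.

    E = n_comparisons * (1 - exp(-exp(-(z - mu)/sigma))), the Gumbel upper
    tail scaled by the number of comparisons. At z = mu the tail is
    1 - 1/e ~ 0.632.
    """
    if cal.evd_mu is None or cal.evd_sigma is None:
        raise ValueError("EVD parameters not calibrated; run calibrate_evd first")
    if cal.evd_sigma <= 0:
        raise ValueError("EVD sigma must be positive")
    tail = -math.expm1(-math.exp(-(z - cal.evd_mu) / cal.evd_sigma))
    return float(cal.n_comparisons * tail)


# --- fingerprint backends --------------------------------------------------

def hashed_fingerprint(molecule: str, n_bits: int = 1024, kmin: int = 2, kmax: int = 4) -> np.ndarray:
    """Deterministic hashed-substring fingerprint of a molecule string.

    Every substring of length kmin..kmax sets one bit chosen by a stable
    hash. Purely lexical — it captures shared substructure strings, which
    is sufficient for set-level similarity screening without a chemistry
    toolkit; swap in a Morgan backend for real molecules.
    """
    fp = np.zeros(n_bits, dtype=bool)
    s = molecule.strip()
    for k in range(kmin, kmax + 1):
        for i in range(max(0, len(s) - k + 1)):
            h = hashlib.blake2b(s[i : i + k].encode(), digest_size=8).digest()
            fp[int.from_bytes(h, "little") % n_bits] = True
    return fp


def fingerprint_molecules(
    molecules: Sequence[str], n_bits: int = 1024, backend: str = "hashed"
) -> np.ndarray:
    """Fingerprint a list of molecule strings with the chosen backend."""
    if backend == "hashed":
        return np.stack([hashed_fingerprint(m, n_bits) for m in molecules])
    if backend == "morgan":
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        fps = []
        for smi in molecules:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"unparsable SMILES: {smi!r}")
            fps.append(np.array(gen.GetFingerprintAsNumPy(mol), dtype=bool))
        return np.stack(fps)
    raise ValueError(f"unknown backend {backend!r}")
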