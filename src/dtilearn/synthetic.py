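"""Synthetic drug-target worlds with a planted, learnable interaction signal.

The generator stands in for the curated benchmark collections (enzyme, ion
channel, GPCR, nuclear receptor): it emits pseudo-PSSMs, sparse 881-bit
fingerprints and a bipartite interaction network in the exact on-disk
formats the pipeline consumes.  Every drug and target carries a latent
compatibility vector; a pair interacts iff the latent inner product ranks
among the top ``n_positives``, and the same latents drive the features, so
the interaction rule is recoverable from the features alone.  ``noise_sd``
corrupts both feature channels; at 0 the signal is clean, at extreme values
the features are pure noise and no classifier can beat chance.

Protein latents enter the PSSM as smooth positional waves (low-order
Legendre shapes of the normalized residue position) mixed across amino-acid
columns, which the Legendre-moment featurizer picks up regardless of
protein length.  Drug latents tilt the per-key Bernoulli logits of the
fingerprint.  Scores are integer-rounded into the PSI-BLAST-like range
[-10, 12] so parsing and normalization run exactly as on real files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import InteractionDataset, balanced_negative_sampling
from .fingerprints import FINGERPRINT_LENGTH, SubstructureFingerprint, write_fingerprint_table
from .legendre import legendre_vandermonde
from .pssm import DEFAULT_ALPHABET, PSSM, ProteinRecord, write_psiblast_pssm
from .evaluation import write_pairs_tsv

__all__ = [
    "SyntheticWorldConfig",
    "generate_protein_pssm",
    "generate_fingerprint",
    "generate_interaction_dataset",
    "write_world",
]

SCORE_MIN, SCORE_MAX = -10, 12

# Fixed structural seed: the latent->feature projections are part of the
# world's definition, shared by every protein/drug and independent of the
# per-entity sampling seeds.
_STRUCTURE_SEED = 987654321

#: Amplitude of the latent signal in PSSM score units and in fingerprint
#: logit units.  Chosen so the planted structure dominates rounding error
#: (PSSM) and per-bit Bernoulli noise (fingerprint) but stays well inside
#: the clipped score range.
_PSSM_SIGNAL_SCALE = 6.0
_FP_LOGIT_SCALE = 6.0


@dataclass
class SyntheticWorldConfig:
    """Study-scale parameters of one synthetic drug-target world.

    Defaults mirror the nuclear-receptor benchmark scale: 54 drugs,
    26 targets, 90 interacting pairs.
    """

    n_drugs: int = 54
    n_targets: int = 26
    n_positives: int = 90
    protein_length_range: tuple[int, int] = (300, 700)
    fingerprint_density: float = 0.2
    latent_dim: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_targets < 1:
            raise ValueError("need at least one drug and one target")
        if self.n_positives > self.n_drugs * self.n_targets / 2:
            raise ValueError(
                "n_positives may not exceed half the network "
                f"({self.n_drugs * self.n_targets // 2})"
            )
        lo, hi = self.protein_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein length range")
        if not 0.0 < self.fingerprint_density < 1.0:
            raise ValueError("fingerprint_density must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _aa_mixing_matrix(latent_dim: int) -> np.ndarray:
    """Fixed unit-norm amino-acid column patterns, one per latent axis."""
    rng = np.random.default_rng(_STRUCTURE_SEED)
    M = rng.normal(size=(latent_dim, 20))
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _fp_projection(latent_dim: int) -> np.ndarray:
    """Fixed unit-norm per-key logit directions for the fingerprint."""
    rng = np.random.default_rng(_STRUCTURE_SEED + 1)
    W = rng.normal(size=(FINGERPRINT_LENGTH, latent_dim))
    return W / np.linalg.norm(W, axis=1, keepdims=True)


def generate_protein_pssm(length: int, latent_vector, noise_sd: float = 0.0,
                          seed: int = 0, protein_id: str = "") -> PSSM:
    """A pseudo-PSSM whose smooth positional structure encodes the latent.

    Row i at normalized position x_i carries a baseline wave plus
    sum_k latent[k] * P_{k+1}(x_i) * aa_pattern_k, scaled, noised, rounded
    to integers and clipped into [-10, 12].
    """
    if length < 1:
        raise ValueError("protein length must be >= 1")
    latent = np.asarray(latent_vector, dtype=float).ravel()
    rng = np.random.default_rng(seed)

    i = np.arange(1, length + 1, dtype=float)
    x = (2 * i - length - 1) / length  # cell centers on [-1, 1]
    # Legendre shapes of order 1..latent_dim carry the signal
    V = legendre_vandermonde(latent.size, x)  # (latent_dim+1, length)
    aa = _aa_mixing_matrix(latent.size)  # (latent_dim, 20)
    signal = (latent[:, None] * V[1:]).T @ aa  # (length, 20)

    baseline = 1.5 * np.cos(np.pi * x)[:, None] + rng.normal(0.0, 0.2, size=(1, 20))
    raw = baseline + _PSSM_SIGNAL_SCALE * signal
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    scores = np.clip(np.rint(raw), SCORE_MIN, SCORE_MAX)

    seq = "".join(DEFAULT_ALPHABET[k] for k in rng.integers(0, 20, size=length))
    return PSSM(
        protein_id=protein_id,
        scores=scores,
        record=ProteinRecord(protein_id=protein_id, sequence=seq),
    )


def generate_fingerprint(latent_vector, density: float = 0.1, seed: int = 0,
                         noise_sd: float = 0.0, drug_id: str = "") -> SubstructureFingerprint:
    """A sparse fingerprint whose on-probabilities encode the drug latent.

    Bit k fires with probability sigmoid(logit(density) + c * w_k . latent),
    with fixed seeded directions w_k, so fingerprints of latently similar
    drugs are correlated.  ``noise_sd`` adds per-bit logit noise.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    latent = np.asarray(latent_vector, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    W = _fp_projection(latent.size)
    modulation = _FP_LOGIT_SCALE * (W @ latent)

    def mean_p(base: float) -> float:
        return float(np.mean(_stable_sigmoid(base + modulation)))

    # calibrate the shared base logit so the expected popcount is exactly
    # 881 * density despite the convexity of the logistic in its tails
    lo, hi = np.log(density / (1.0 - density)) - 12.0, np.log(density / (1.0 - density)) + 12.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < density:
            lo = mid
        else:
            hi = mid
    logits = 0.5 * (lo + hi) + modulation
    if noise_sd > 0:
        logits = logits + rng.normal(0.0, noise_sd, size=logits.shape)
    p = _stable_sigmoid(logits)
    bits = (rng.random(FINGERPRINT_LENGTH) < p).astype(np.int8)
    return SubstructureFingerprint(drug_id=drug_id, bits=bits)


def generate_interaction_dataset(
    config: SyntheticWorldConfig,
) -> tuple[InteractionDataset, dict[str, PSSM], dict[str, SubstructureFingerprint]]:
    """Build a full synthetic world: network, pseudo-PSSMs and fingerprints.

    Latent vectors are drawn per drug and per target; the ``n_positives``
    pairs with the largest latent inner products are the interacting set,
    and balanced negatives are drawn uniformly from the rest.
    """
    rng = np.random.default_rng(config.seed)
    drug_ids = [f"D{i + 1:04d}" for i in range(config.n_drugs)]
    target_ids = [f"T{i + 1:04d}" for i in range(config.n_targets)]

    # Centered unit-norm latents: iteratively centering and renormalizing
    # makes every latent lie on the sphere with (near-)zero population mean.
    # Zero mean kills the linear/marginal component of the inner product, so
    # no drug or target is intrinsically promiscuous and the interaction rule
    # cannot be predicted from entity identity alone; unit norms equalize the
    # spread of each entity's compatibility scores.  What remains is a pure
    # pairwise-compatibility signal.
    def _centered_sphere(n: int) -> np.ndarray:
        Z = rng.normal(size=(n, config.latent_dim))
        for _ in range(25):
            Z = Z - Z.mean(axis=0)
            Z = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        return Z

    drug_latents = _centered_sphere(config.n_drugs)
    target_latents = _centered_sphere(config.n_targets)

    compat = drug_latents @ target_latents.T  # (n_drugs, n_targets)
    flat = compat.ravel()
    top = np.argsort(-flat)[: config.n_positives]
    positives = [
        (drug_ids[k // config.n_targets], target_ids[k % config.n_targets])
        for k in sorted(top)
    ]

    dataset = balanced_negative_sampling(
        InteractionDataset(drugs=drug_ids, targets=target_ids, positives=positives),
        seed=config.seed,
    )

    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_targets)
    pssms = {
        tid: generate_protein_pssm(
            int(lengths[j]), target_latents[j], config.noise_sd,
            seed=config.seed * 100003 + j, protein_id=tid,
        )
        for j, tid in enumerate(target_ids)
    }
    fingerprints = {
        did: generate_fingerprint(
            drug_latents[j], config.fingerprint_density,
            seed=config.seed * 200003 + j, noise_sd=config.noise_sd, drug_id=did,
        )
        for j, did in enumerate(drug_ids)
    }
    return dataset, pssms, fingerprints


def write_world(config: SyntheticWorldConfig, out_dir) -> dict[str, Path]:
    """Materialize a world on disk in the pipeline's input formats.

    Creates ``pssms/<target>.pssm`` files, ``fingerprints.tsv`` and
    ``pairs.tsv`` under *out_dir*; returns the paths.
    """
    out_dir = Path(out_dir)
    dataset, pssms, fingerprints = generate_interaction_dataset(config)
    pssm_dir = out_dir / "pssms"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    for tid, pssm in pssms.items():
        write_psiblast_pssm(pssm, pssm_dir / f"{tid}.pssm")
    fp_path = out_dir / "fingerprints.tsv"
    write_fingerprint_table(list(fingerprints.values()), fp_path)
    pairs_path = out_dir / "pairs.tsv"
    write_pairs_tsv(dataset, pairs_path)
    return {"pssm_dir": pssm_dir, "fingerprints": fp_path, "pairs": pairs_path}
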