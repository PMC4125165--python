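"""Seeded generators for spectra, qPCR datasets and opsin sequences.

Every generator is a deterministic function of its configuration and
seed, attaches the generating ground truth to its output, and is the
exact inverse of its consuming pipeline stage at zero noise:
noise-free spectra refit to their true λ_max, noise-free Ct tables
invert to their true expression proportions, and synthesised opsins
report exactly the residues they were given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msp import Spectrum
from .qpcr import QpcrRecord
from .templates import evaluate_template
from .tuning import REGISTRIES, SiteRegistry, load_reference

__all__ = [
    "SpectrumSimConfig",
    "QpcrSimConfig",
    "simulate_spectra",
    "simulate_mixture",
    "simulate_qpcr",
    "synthesize_opsin",
    "consensus_scaffold",
]


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Conditions for one simulated photoreceptor population.

    Defaults emulate rod microspectrophotometry: a 350–750 nm scan at
    1 nm steps and additive Gaussian noise with SD 0.02 of the
    normalised peak, which reproduces per-cell λ_max quality SDs of a
    few nm.
    """

    true_lambda_max: float
    chromophore: str = "A1"
    n_cells: int = 60
    noise_sd: float = 0.02
    peak_scale: float = 1.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0  # per nm
    wavelength_start: float = 350.0
    wavelength_stop: float = 750.0
    wavelength_step: float = 1.0
    stage: str = "glass"
    cell_type: str = "rod"
    n_specimens: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be ≥ 1")
        if not (
            self.wavelength_start <= self.true_lambda_max - 80
            and self.true_lambda_max + 80 <= self.wavelength_stop
        ):
            raise ValueError("wavelength range must cover true_lambda_max ± 80 nm")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_start,
            self.wavelength_stop + self.wavelength_step / 2,
            self.wavelength_step,
        )


def simulate_spectra(
    config: SpectrumSimConfig, id_prefix: str = "cell"
) -> list[Spectrum]:
    """Simulate absorbance traces for one photoreceptor population.

    Each trace is ``peak_scale × template + linear baseline + iid
    Gaussian noise``.  Cells are assigned round-robin to
    ``n_specimens`` specimens.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    template = evaluate_template(
        config.true_lambda_max, config.chromophore, wl
    ).relative_absorbance
    baseline = config.baseline_offset + config.baseline_slope * (wl - wl[0])
    out = []
    for i in range(config.n_cells):
        noise = rng.normal(0.0, config.noise_sd, wl.size) if config.noise_sd else 0.0
        out.append(
            Spectrum(
                cell_id=f"{id_prefix}_{config.stage}_{i:04d}",
                specimen_id=f"spec_{config.stage}_{i % config.n_specimens}",
                stage=config.stage,
                cell_type=config.cell_type,
                wavelengths=wl.copy(),
                absorbance=config.peak_scale * template + baseline + noise,
                truth={
                    "lambda_max": config.true_lambda_max,
                    "chromophore": config.chromophore,
                },
            )
        )
    return out


def simulate_mixture(
    config_a1: SpectrumSimConfig,
    config_a2: SpectrumSimConfig,
    seed: int = 0,
) -> list[Spectrum]:
    """Union of an A1 and an A2 population, order shuffled by seed.

    Counts are exact (``n_cells`` from each config); ground-truth
    chromophore labels travel with each spectrum.
    """
    if config_a1.chromophore != "A1" or config_a2.chromophore != "A2":
        raise ValueError("configs must be (A1, A2) in that order")
    pool = simulate_spectra(config_a1, id_prefix="a1") + simulate_spectra(
        config_a2, id_prefix="a2"
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


@dataclass(frozen=True)
class QpcrSimConfig:
    """Conditions for one simulated qPCR sample.

    ``true_proportions`` are the generating fractions of total opsin
    expression; Ct values are derived by inverting the
    proportional-expression formula (with equal efficiencies,
    Ct_i = C0 − log_{1+E} of relative abundance) so the pipeline
    recovers the proportions exactly at zero replicate noise.
    """

    true_proportions: dict[str, float]
    efficiencies: dict[str, float] = field(default_factory=dict)
    housekeeping_genes: tuple[str, ...] = ("cytb", "ARP")
    housekeeping_ct: float = 18.0
    anchor_ct: float = 20.0  # Ct of the most abundant gene
    replicate_noise_sd: float = 0.0
    n_replicates: int = 3
    sample_id: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.true_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"true proportions sum to {total}, expected 1")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate noise SD must be non-negative")
        for gene, e in self.efficiencies.items():
            if not (0 < e <= 1):
                raise ValueError(f"{gene}: efficiency must lie in (0, 1]")


def simulate_qpcr(config: QpcrSimConfig) -> list[QpcrRecord]:
    """Generate replicate-averaged Ct records for one sample.

    Genes with true proportion 0 are emitted as undetected (Ct NaN).
    Housekeeping genes are generated at ``housekeeping_ct``.
    """
    rng = np.random.default_rng(config.seed)
    eff = {g: config.efficiencies.get(g, 1.0) for g in config.true_proportions}

    detected = {g: p for g, p in config.true_proportions.items() if p > 0}
    p_max = max(detected.values())
    records = []
    for gene, p in config.true_proportions.items():
        if p == 0:
            ct: float = float("nan")
        else:
            # (1+E)^(−Ct) ∝ p, anchored so the most abundant gene sits
            # at anchor_ct
            ct = config.anchor_ct - math.log(p / p_max) / math.log(1 + eff[gene])
            if config.replicate_noise_sd:
                reps = ct + rng.normal(
                    0.0, config.replicate_noise_sd, config.n_replicates
                )
                ct = float(reps.mean())
        records.append(
            QpcrRecord(
                gene=gene,
                sample_id=config.sample_id,
                ct=ct,
                efficiency=eff[gene],
                is_housekeeping=False,
            )
        )
    for gene in config.housekeeping_genes:
        ct = config.housekeeping_ct
        if config.replicate_noise_sd:
            reps = ct + rng.normal(
                0.0, config.replicate_noise_sd, config.n_replicates
            )
            ct = float(reps.mean())
        records.append(
            QpcrRecord(
                gene=gene,
                sample_id=config.sample_id,
                ct=ct,
                efficiency=config.efficiencies.get(gene, 1.0),
                is_housekeeping=True,
            )
        )
    return records


def consensus_scaffold(opsin_class: str) -> str:
    """Reference backbone carrying the class consensus at known sites.

    Starts from the bovine rhodopsin reference and substitutes the
    class-consensus residue at every known tuning site, so reference
    numbering holds trivially for synthesised sequences.
    """
    registry = REGISTRIES[opsin_class]
    seq = list(load_reference())
    for site, residue in registry.consensus.items():
        seq[site - 1] = residue
    return "".join(seq)


def synthesize_opsin(
    opsin_class: str,
    assignments: dict[int, str] | None = None,
    deletions: tuple[tuple[int, int], ...] = (),
    insertions: tuple[tuple[int, str], ...] = (),
) -> tuple[str, dict[int, int]]:
    """Build a synthetic opsin with known residues at registry sites.

    Parameters
    ----------
    opsin_class
        Registry class providing the consensus scaffold.
    assignments
        Reference position → residue to place there (e.g. ``{292: "A"}``).
    deletions
        ``(start, length)`` pairs in reference coordinates; the residues
        at positions start..start+length−1 are removed.
    insertions
        ``(after, segment)`` pairs: ``segment`` is inserted after the
        reference position ``after``.

    Returns
    -------
    (sequence, truth_map)
        The synthetic sequence and the ground-truth map of reference
        position → 1-based query position for all surviving residues.
    """
    registry: SiteRegistry = REGISTRIES[opsin_class]
    scaffold = list(consensus_scaffold(opsin_class))
    for site, residue in (assignments or {}).items():
        if not (1 <= site <= len(scaffold)):
            raise ValueError(f"site {site} outside reference")
        scaffold[site - 1] = residue

    deleted = set()
    for start, length in deletions:
        deleted.update(range(start, start + length))
    for site in registry.sites:
        if site in deleted:
            raise ValueError(f"deletion removes registered site {site}")

    ins_after = {after: segment for after, segment in insertions}
    seq_parts: list[str] = []
    truth: dict[int, int] = {}
    if 0 in ins_after:
        seq_parts.append(ins_after[0])
    for ref_pos, residue in enumerate(scaffold, start=1):
        if ref_pos not in deleted:
            seq_parts.append(residue)
            truth[ref_pos] = sum(len(p) for p in seq_parts)
        if ref_pos in ins_after and ref_pos != 0:
            seq_parts.append(ins_after[ref_pos])
    return "".join(seq_parts), truth
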