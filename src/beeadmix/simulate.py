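"""Synthetic colonies with known ancestry ground truth.

The generator emulates the sampling design the estimators assume: a panel of
L ancestry-informative SNPs whose reference-allele frequencies diverge
between the A / M / C lineages, colonies headed by one diploid queen mated to
``n_drones`` haploid drones (12 by default, a conservative queen mating
frequency), and a pooled sample of ``n_workers`` workers (20 by default,
i.e. 40 allele copies) genotyped as pooled allele counts.

Two observation models are available:

``idealized``
    Pooled counts are drawn directly as Binomial(n_alleles, p_j) with p_j the
    lineage-mixture frequency — exactly the model the maximum-likelihood
    estimator assumes.
``family``
    The colony pedigree is simulated explicitly: each queen gamete's lineage
    origin is drawn per locus, each drone carries a whole haploid genome from
    a single lineage, every worker inherits one queen allele per locus and
    the genome of a uniformly assigned father drone (multinomial patrilines).
    Pooled counts sum the 2 x n_workers worker alleles, so the pooled
    frequency equals the mean of the workers' individual genotypic
    frequencies exactly — the idealization of the pooled-vs-individual
    concordance the design relies on.  Shared parents correlate workers, so
    pooled counts are overdispersed relative to the binomial model.

Maternal (mtDNA) lineage is drawn independently of the nuclear admixture
vector, which makes deliberate mito-nuclear discordance scenarios possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import ColonyObservation, LineagePanel, write_colonies, write_panel

REGIONS = ("North", "Central Highlands", "Pacific Coast", "Gulf Coast", "Yucatan Peninsula")
# maternal lineage weights over (A, M, C): African haplotypes dominate in the
# Americas, Eastern European are the common European maternal line, Western
# European maternal lines are rare
DEFAULT_MATERNAL_PROBS = (0.58, 0.02, 0.40)
DNA = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-colony generator.

    Defaults mirror the study design: 94 SNPs, 20 pooled workers (40 allele
    copies), 12 drone matings, and a country-wide mean admixture of
    (A, M, C) = (0.59, 0.17, 0.24).
    """

    seed: int = 0
    n_snps: int = 94
    panel_mode: str = "diagnostic"  # diagnostic | beta
    beta_shape: tuple[float, float] = (0.5, 0.5)
    diagnostic_eps: float = 0.01
    true_admixture: tuple[float, float, float] = (0.59, 0.17, 0.24)
    admixture_concentration: float | None = None  # per-colony Dirichlet spread
    n_drones: int = 12
    n_workers: int = 20
    sampling_mode: str = "idealized"  # idealized | family
    n_colonies: int = 50
    n_apiaries: int = 5
    feral_fraction: float = 0.29
    maternal_lineage_probs: tuple[float, float, float] = DEFAULT_MATERNAL_PROBS
    seq_length: int = 600
    between_lineage_substitutions: int = 10
    within_lineage_mutations: int = 2

    def __post_init__(self) -> None:
        t = np.asarray(self.true_admixture, float)
        if t.min() < 0 or abs(t.sum() - 1.0) > 1e-9:
            raise ValueError(f"true_admixture must lie on the simplex, got {tuple(t)}")
        for name in ("n_snps", "n_drones", "n_workers", "n_colonies", "n_apiaries", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.panel_mode not in ("diagnostic", "beta"):
            raise ValueError(f"unknown panel_mode {self.panel_mode!r}")
        if self.sampling_mode not in ("idealized", "family"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")
        m = np.asarray(self.maternal_lineage_probs, float)
        if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("maternal_lineage_probs must be a probability vector over (A, M, C)")

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_workers


@dataclass
class SimulatedTruth:
    """Ground truth for one simulated colony."""

    colony_id: str
    true_admixture: tuple[float, float, float]
    maternal_lineage: str
    drone_lineages: list[str] = field(default_factory=list)
    worker_frequencies: np.ndarray | None = None  # family mode: per-SNP worker means
    seed: int = 0


def simulate_panel(config: SimulationConfig, rng: np.random.Generator | None = None) -> LineagePanel:
    """Generate a lineage reference panel.

    ``diagnostic`` mode cycles SNPs through patterns where one lineage has
    frequency ``1 - eps`` and the other two ``eps``, giving per-SNP divergence
    ``1 - 2*eps`` (maximally informative; eps > 0 keeps every likelihood
    finite).  ``beta`` mode draws each lineage frequency independently from
    Beta(beta_shape), emulating panels of varying informativeness.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.n_snps
    if config.panel_mode == "diagnostic":
        eps = config.diagnostic_eps
        freqs = np.full((3, L), eps)
        for j in range(L):
            freqs[j % 3, j] = 1.0 - eps
    else:
        a, b = config.beta_shape
        freqs = rng.beta(a, b, size=(3, L))
    snp_ids = [f"snp{j + 1:04d}" for j in range(L)]
    return LineagePanel(snp_ids, freqs)


def _mixture_p(panel: LineagePanel, truth: Sequence[float]) -> np.ndarray:
    return np.asarray(truth, float) @ panel.freqs


def simulate_colony(
    panel: LineagePanel,
    truth: Sequence[float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    colony_id: str = "sim1",
) -> tuple[ColonyObservation, SimulatedTruth]:
    """Simulate one colony's pooled allele counts and its ground truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = np.asarray(truth, float)
    if t.min() < 0 or abs(t.sum() - 1.0) > 1e-9:
        raise ValueError(f"truth vector must lie on the simplex, got {tuple(t)}")
    L = panel.n_snps
    n_alleles = config.n_alleles
    maternal = str(rng.choice(["A", "M", "C"], p=config.maternal_lineage_probs))

    if config.sampling_mode == "idealized":
        p = _mixture_p(panel, t)
        counts = rng.binomial(n_alleles, p)
        truth_rec = SimulatedTruth(colony_id, tuple(t), maternal, seed=config.seed)
    else:
        # explicit pedigree: queen gamete lineages per locus, one lineage per drone
        d, w = config.n_drones, config.n_workers
        queen_lin = rng.choice(3, size=(2, L), p=t)  # maternal genome copies
        queen_alleles = (rng.random((2, L)) < panel.freqs[queen_lin, np.arange(L)]).astype(int)
        drone_lin = rng.choice(3, size=d, p=t)
        drone_alleles = (rng.random((d, L)) < panel.freqs[drone_lin]).astype(int)
        fathers = rng.integers(0, d, size=w)  # multinomial patrilines
        queen_pick = rng.integers(0, 2, size=(w, L))  # Mendelian segregation
        worker_maternal = queen_alleles[queen_pick, np.arange(L)]
        worker_paternal = drone_alleles[fathers]
        worker_geno = worker_maternal + worker_paternal  # (w, L) in {0,1,2}
        counts = worker_geno.sum(axis=0)
        truth_rec = SimulatedTruth(
            colony_id,
            tuple(t),
            maternal,
            drone_lineages=[("A", "M", "C")[i] for i in drone_lin],
            worker_frequencies=worker_geno / 2.0,
            seed=config.seed,
        )

    obs = ColonyObservation(
        colony_id=colony_id,
        counts=counts,
        n_alleles=n_alleles,
        maternal_lineage=maternal,
    )
    return obs, truth_rec


def simulate_dataset(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> tuple[LineagePanel, list[ColonyObservation], list[SimulatedTruth]]:
    """Simulate a panel plus ``n_colonies`` colonies grouped into apiaries.

    Colonies are assigned round-robin to apiaries; each apiary carries a
    beekeeping-region label and each colony a managed/feral label drawn with
    ``feral_fraction``.  When ``out_dir`` is given, the panel, the colony
    table and a truth table are written in the package's delimited-text
    formats.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pan = simulate_panel(config, rng)

    if config.admixture_concentration is not None:
        alpha = np.asarray(config.true_admixture) * config.admixture_concentration
        truths = rng.dirichlet(np.maximum(alpha, 1e-6), size=config.n_colonies)
    else:
        truths = np.tile(np.asarray(config.true_admixture, float), (config.n_colonies, 1))

    colonies: list[ColonyObservation] = []
    truth_recs: list[SimulatedTruth] = []
    for k in range(config.n_colonies):
        cid = f"colony{k + 1:04d}"
        obs, tr = simulate_colony(pan, truths[k], config, rng, colony_id=cid)
        a = k % config.n_apiaries
        obs.apiary_id = f"apiary{a + 1:02d}"
        obs.region = REGIONS[a % len(REGIONS)]
        obs.management = "feral" if rng.random() < config.feral_fraction else "managed"
        obs.latitude = float(rng.uniform(15.0, 30.0))
        obs.longitude = float(rng.uniform(-110.0, -88.0))
        obs.altitude = float(rng.uniform(0.0, 2500.0))
        colonies.append(obs)
        truth_recs.append(tr)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(pan, out / "panel.csv")
        write_colonies(colonies, pan, out / "colonies.csv")
        truth_table(truth_recs).to_csv(out / "truth.csv", index=False)
    return pan, colonies, truth_recs


def truth_table(truths: Iterable[SimulatedTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "colony_id": [t.colony_id for t in truths],
            "true_A": [t.true_admixture[0] for t in truths],
            "true_M": [t.true_admixture[1] for t in truths],
            "true_C": [t.true_admixture[2] for t in truths],
            "maternal_lineage": [t.maternal_lineage for t in truths],
            "seed": [t.seed for t in truths],
        }
    )


# ---------------------------------------------------------------------------
# mtDNA sequence simulation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each given position with a different base."""
    out = seq.copy()
    for p in positions:
        choices = DNA[DNA != out[p]]
        out[p] = rng.choice(choices)
    return out


def simulate_haplotypes(
    config: SimulationConfig,
    maternal_lineages: Sequence[str],
    colony_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Simulate lineage reference sequences and one sequence per colony.

    One ancestral sequence is built per lineage (A, M, C, O, Y) by mutating a
    common root at lineage-private positions, so ancestors differ pairwise by
    at least ``between_lineage_substitutions`` sites (twice that, by
    construction).  Each colony sequence is its maternal lineage's ancestor
    with at most ``within_lineage_mutations`` random substitutions.  Requires
    ``between_lineage_substitutions > 2 * within_lineage_mutations`` so that
    nearest-reference classification is unambiguous.

    Returns ``(references, colony_seqs)`` as dicts of name -> sequence;
    reference names follow the ``lineage|name`` convention.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    B, W = config.between_lineage_substitutions, config.within_lineage_mutations
    if B <= 2 * W:
        raise ValueError(
            f"separability requires between_lineage_substitutions ({B}) > "
            f"2 * within_lineage_mutations ({W})"
        )
    lineages = ("A", "M", "C", "O", "Y")
    if config.seq_length < B * len(lineages):
        raise ValueError("seq_length too short for the requested lineage divergence")

    root = rng.choice(DNA, size=config.seq_length)
    # disjoint private position blocks -> pairwise distance exactly 2B >= B
    positions = rng.permutation(config.seq_length)
    ancestors: dict[str, np.ndarray] = {}
    for i, lin in enumerate(lineages):
        private = positions[i * B : (i + 1) * B]
        ancestors[lin] = _mutate(root, private, rng)
    references = {f"{lin}|ref_{lin}1": "".join(ancestors[lin]) for lin in lineages}

    if colony_ids is None:
        colony_ids = [f"colony{k + 1:04d}" for k in range(len(maternal_lineages))]
    colony_seqs: dict[str, str] = {}
    for cid, lin in zip(colony_ids, maternal_lineages):
        n_mut = int(rng.integers(0, W + 1))
        pos = rng.choice(config.seq_length, size=n_mut, replace=False)
        colony_seqs[cid] = "".join(_mutate(ancestors[lin], pos, rng))
    return references, colony_seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
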