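"""Group-level ancestry summaries and the mitochondrial-vs-nuclear comparison.

Colonies are aggregated by apiary or by beekeeping region x management.  For
each group and lineage two ancestry proportions are compared:

* the **mitochondrial** proportion — the fraction of colonies whose maternal
  lineage is the target lineage, with a Wald interval at n = number of
  colonies with a known lineage;
* the **nuclear** proportion — the mean estimated admixture fraction across
  colonies, with a Wald interval at an effective allele count of
  ``(2 + drone_matings) * n_colonies``: every colony contributes the queen's
  two alleles plus one haploid allele per drone mate (12 by default, a
  conservative queen mating frequency).

Both intervals use CI = p-hat +/- z * sqrt(p-hat * (1 - p-hat) / n) with
z = 1.96 for 95%.  Applying the binomial-proportion formula to mean admixture
fractions is a deliberate fidelity choice: admixture means are not binomial
counts, but the effective-allele-count interval is the field's convention for
this comparison.  Overlapping intervals are read as "not distinguishable";
otherwise the side with the higher point estimate wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NUCLEAR_LINEAGES = ("A", "M", "C")
DEFAULT_Z = 1.96


@dataclass
class ProportionCI:
    """A proportion with its Wald interval at a stated effective sample size."""

    p_hat: float
    n_effective: int
    z: float = DEFAULT_Z
    lower: float = 0.0
    upper: float = 0.0
    degenerate_flag: bool = False

    def overlaps(self, other: "ProportionCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


def nuclear_effective_n(n_colonies: int, drone_matings: int = 12) -> int:
    """Effective allele count behind a group's mean nuclear ancestry.

    Each colony contributes the queen's two alleles plus one haploid allele
    per drone mate: ``(2 + drone_matings) * n_colonies``.
    """
    if n_colonies < 1 or drone_matings < 1:
        raise ValueError("n_colonies and drone_matings must be positive")
    return (2 + drone_matings) * n_colonies


def proportion_ci(p_hat: float, n_effective: int, z: float = DEFAULT_Z) -> ProportionCI:
    """Wald interval p-hat +/- z*sqrt(p-hat(1-p-hat)/n), truncated to [0, 1].

    At p-hat of exactly 0 or 1 the formula collapses to a zero-width interval;
    the ``degenerate_flag`` marks it.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    if n_effective < 1:
        raise ValueError(f"n_effective must be >= 1, got {n_effective}")
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n_effective)
    return ProportionCI(
        p_hat=p_hat,
        n_effective=n_effective,
        z=z,
        lower=max(0.0, p_hat - half),
        upper=min(1.0, p_hat + half),
        degenerate_flag=(p_hat in (0.0, 1.0)),
    )


def compare_mt_vs_nuclear(mito: ProportionCI, nuclear: ProportionCI) -> str:
    """Verdict from the CI-overlap rule.

    ``not_distinguishable`` when the intervals overlap; otherwise
    ``mito_higher`` or ``nuclear_higher`` by the point estimates.
    """
    if mito is None or nuclear is None:
        raise ValueError("both confidence intervals are required")
    if mito.overlaps(nuclear):
        return "not_distinguishable"
    return "mito_higher" if mito.p_hat > nuclear.p_hat else "nuclear_higher"


@dataclass
class GroupAncestrySummary:
    """Mitochondrial and nuclear ancestry of one colony group."""

    group_key: tuple[str, ...]
    n_colonies: int
    n_mito_known: int
    mito_proportions: dict[str, ProportionCI] = field(default_factory=dict)
    nuclear_proportions: dict[str, ProportionCI] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)
    small_group_flag: bool = False


def summarize_groups(
    estimates: pd.DataFrame,
    mito_lineages: Mapping[str, str],
    metadata: pd.DataFrame,
    grouping: Sequence[str] = ("region", "management"),
    drone_matings: int = 12,
    z: float = DEFAULT_Z,
    min_group_size: int = 3,
) -> list[GroupAncestrySummary]:
    """Per-group mito and nuclear ancestry with CIs and overlap verdicts.

    ``estimates`` is the admixture table (``colony_id, A, M, C``),
    ``mito_lineages`` maps colony id -> maternal lineage label, ``metadata``
    carries the grouping columns keyed by ``colony_id``.  Colonies that fail
    to join are reported and skipped; groups smaller than ``min_group_size``
    are flagged.  Mito proportions are computed over colonies with a known
    lineage; lineages O and Y appear in mito summaries but have no nuclear
    counterpart (and no verdict), the SNP panel spanning A/M/C only.
    """
    est = estimates.dropna(subset=["A", "M", "C"]).copy()
    meta_cols = ["colony_id", *grouping]
    missing_cols = [c for c in meta_cols if c not in metadata.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks columns {missing_cols}")
    joined = est.merge(metadata[meta_cols], on="colony_id", how="left")
    lost = joined[joined[list(grouping)].isna().any(axis=1)]["colony_id"].tolist()
    if lost:
        logger.warning("colonies with no metadata join: %s", lost)
        joined = joined.dropna(subset=list(grouping))

    summaries: list[GroupAncestrySummary] = []
    for key, grp in joined.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        if n == 0:
            continue
        labels = [mito_lineages.get(cid, "unknown") for cid in grp["colony_id"]]
        known = [l for l in labels if l != "unknown"]
        n_known = len(known)

        mito_cis: dict[str, ProportionCI] = {}
        observed_lineages = sorted(set(known) | set(NUCLEAR_LINEAGES))
        if n_known:
            for lin in observed_lineages:
                p = known.count(lin) / n_known
                mito_cis[lin] = proportion_ci(p, n_known, z)

        n_eff = nuclear_effective_n(n, drone_matings)
        nuc_cis = {
            lin: proportion_ci(float(grp[lin].mean()), n_eff, z) for lin in NUCLEAR_LINEAGES
        }
        verdicts = {}
        for lin in NUCLEAR_LINEAGES:
            if lin in mito_cis:
                verdicts[lin] = compare_mt_vs_nuclear(mito_cis[lin], nuc_cis[lin])
        summaries.append(
            GroupAncestrySummary(
                group_key=tuple(str(k) for k in key),
                n_colonies=n,
                n_mito_known=n_known,
                mito_proportions=mito_cis,
                nuclear_proportions=nuc_cis,
                verdicts=verdicts,
                small_group_flag=n < min_group_size,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[GroupAncestrySummary]) -> pd.DataFrame:
    """Long-format table: one row per group x lineage."""
    rows = []
    for s in summaries:
        lineages = sorted(set(s.mito_proportions) | set(s.nuclear_proportions))
        for lin in lineages:
            m = s.mito_proportions.get(lin)
            nu = s.nuclear_proportions.get(lin)
            rows.append(
                {
                    "group": "|".join(s.group_key),
                    "lineage": lin,
                    "n_colonies": s.n_colonies,
                    "n_mito_known": s.n_mito_known,
                    "mito_p": m.p_hat if m else float("nan"),
                    "mito_lower": m.lower if m else float("nan"),
                    "mito_upper": m.upper if m else float("nan"),
                    "nuclear_p": nu.p_hat if nu else float("nan"),
                    "nuclear_lower": nu.lower if nu else float("nan"),
                    "nuclear_upper": nu.upper if nu else float("nan"),
                    "verdict": s.verdicts.get(lin, ""),
                    "small_group_flag": s.small_group_flag,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run the full analysis from a declarative YAML config.

    The config either names input files (``panel``, ``colonies``,
    ``colony_fasta``, ``reference_fasta``) or carries a ``simulate`` mapping
    of :class:`~beeadmix.simulate.SimulationConfig` fields.  Writes
    ``estimates.csv``, ``mito_report.csv``, ``network_edges.csv``,
    ``group_summary.csv`` and ``run_log.txt`` into the output directory and
    returns that directory.  Reruns with the same config and seed are
    byte-identical.
    """
    from . import admixture, mtdna, simulate as sim
    from .panel import load_colonies, load_panel

    config_path = Path(config_path)
    with open(config_path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}

    if out_dir is None:
        if "out_dir" not in cfg:
            raise KeyError("config missing required key 'out_dir'")
        out_dir = cfg["out_dir"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = int(cfg.get("seed", 0))
    log_lines = [f"config: {config_path.name}", f"seed: {seed}"]

    if "simulate" in cfg:
        sim_cfg = sim.SimulationConfig(seed=seed, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg["simulate"].items()
        })
        panel, colonies, truths = sim.simulate_dataset(sim_cfg, out_dir=out / "inputs")
        refs_d, colony_seqs = sim.simulate_haplotypes(
            sim_cfg,
            [t.maternal_lineage for t in truths],
            [t.colony_id for t in truths],
        )
        references = {lin: [seq] for name, seq in refs_d.items() for lin in [name.split("|")[0]]}
        log_lines.append(f"simulated: {sim_cfg}")
    else:
        for key in ("panel", "colonies", "colony_fasta", "reference_fasta"):
            if key not in cfg:
                raise KeyError(f"config missing required key {key!r}")
        panel = load_panel(cfg["panel"])
        colonies = load_colonies(cfg["colonies"], panel, values=cfg.get("values", "auto"))
        colony_seqs = mtdna.read_colony_fasta(cfg["colony_fasta"])
        references = mtdna.read_reference_fasta(cfg["reference_fasta"])
        log_lines.append(f"inputs: {cfg['panel']}, {cfg['colonies']}")

    # nuclear admixture
    estimates = admixture.estimate_batch(colonies, panel, seed=seed)
    estimates.to_csv(out / "estimates.csv", index=False)

    # mtDNA lineage + haplotypes + network
    lineages: dict[str, str] = {}
    rows = []
    for cid, seq in colony_seqs.items():
        lin, dist, amb = mtdna.classify_lineage(mtdna.normalize_sequence(seq), references)
        lineages[cid] = lin
        rows.append({"colony_id": cid, "lineage": lin, "distance": dist, "ambiguous": amb})
    records = mtdna.dedupe_haplotypes(list(colony_seqs.items()), lineages)
    network = mtdna.build_network(records, max_steps=int(cfg.get("max_steps", 10)))
    network.to_frame().to_csv(out / "network_edges.csv", index=False)

    apiaries = {c.colony_id: c.apiary_id for c in colonies}
    african = mtdna.mito_africanization(lineages, apiaries)
    mito_report = pd.DataFrame(rows).merge(
        pd.DataFrame({"colony_id": list(apiaries), "apiary_id": list(apiaries.values())}),
        on="colony_id",
        how="left",
    )
    mito_report.to_csv(out / "mito_report.csv", index=False)
    african.rename_axis("apiary_id").to_frame().to_csv(out / "apiary_africanization.csv")

    # group summaries
    metadata = pd.DataFrame(
        {
            "colony_id": [c.colony_id for c in colonies],
            "apiary_id": [c.apiary_id for c in colonies],
            "region": [c.region for c in colonies],
            "management": [c.management for c in colonies],
        }
    )
    grouping = cfg.get("grouping", ["region", "management"])
    summaries = summarize_groups(estimates, lineages, metadata, grouping=grouping)
    summaries_to_frame(summaries).to_csv(out / "group_summary.csv", index=False)

    log_lines.append(f"n_colonies: {len(colonies)}")
    log_lines.append(f"n_haplotypes: {len(records)}")
    log_lines.append(f"grouping: {grouping}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
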