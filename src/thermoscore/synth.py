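"""Synthetic heat-stress study generator with recorded ground truth.

Emulates the structure of a five-cultivar tomato thermotolerance screen:
one tolerant and one sensitive cultivar plus three intermediates on a
tolerance gradient tau in [0, 1]; two heat regimes (a stepwise 40->50 degC
ramp over 6 h and an acute 50 degC shock for 1 h) against a 25 degC control;
four regulatory gene classes planted in uniform-background promoters:

* HSE and DRE_HSE genes (Hsf-pathway) are induced under BOTH regimes, and
  their acute-shock induction is attenuated in sensitive cultivars
  (attenuation factor s(tau) = s_min + (1 - s_min) * tau applies to acute
  stress only) — tolerant cultivars maintain induction at 50 degC.
* EE and ABRE genes (circadian/ABA pathway) are induced ONLY under the
  stepwise regime.
* background genes are never induced.

Physiology (Fv/Fm, root and shoot weight, leaf wilting index) degrades with
1 - tau.  Everything is driven by one integer seed; identical seed + config
gives bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cisenrich import MOTIF_REGISTRY
from .io import (
    ExpressionStudy,
    PromoterSet,
    SampleInfo,
    ValidationError,
    get_logger,
    write_expression_study,
    write_table,
)

__all__ = ["GeneratorConfig", "TruthRecord", "simulate_study", "truth_ranking", "write_outputs"]

log = get_logger("synthgen")

#: sampling time (h) attached to each treatment's arrays
TREATMENT_TIMES = {"control_25": 0.0, "acute_50": 1.0, "stepwise_40_50": 6.0}

GENE_CLASSES = ("HSE", "DRE_HSE", "EE", "ABRE", "background")

#: motifs planted per promoter for each regulated class
_PLANT_PLAN = {
    "HSE": ("complete_HSE", "complete_HSE"),
    "DRE_HSE": ("complete_HSE", "DRE"),
    "EE": ("EE", "EE"),
    "ABRE": ("ABRE", "ABRE"),
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic screen.

    Defaults: 2000 genes (the scale of a heat-responsive gene set on a
    genome-wide array), five cultivars spanning tau 0.1-0.9, three expression
    replicates, four physiology replicates, 5% of genes per regulated class.
    Effect sizes are log2 units: Hsf-pathway genes average 7 log2 units of
    acute induction in a fully tolerant background and 6 under the ramp;
    EE/ABRE genes average 6 under the ramp and 0 under acute shock.
    """

    n_genes: int = 2000
    cultivar_tau: dict = field(
        default_factory=lambda: {
            "AT": 0.9,   # tolerant reference
            "Mm8": 0.55,
            "Sat": 0.5,
            "RGL": 0.45,
            "SF": 0.1,   # sensitive reference
        }
    )
    n_replicates: int = 3
    n_physio_replicates: int = 4
    class_proportions: dict = field(
        default_factory=lambda: {
            "HSE": 0.05, "DRE_HSE": 0.05, "EE": 0.05, "ABRE": 0.05, "background": 0.80,
        }
    )
    effect_acute: dict = field(
        default_factory=lambda: {"HSE": 7.0, "DRE_HSE": 7.0, "EE": 0.0, "ABRE": 0.0}
    )
    effect_stepwise: dict = field(
        default_factory=lambda: {"HSE": 6.0, "DRE_HSE": 6.0, "EE": 6.0, "ABRE": 6.0}
    )
    effect_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.25
    attenuation_floor: float = 0.5  # s_min: acute induction retained at tau = 0
    upstream_len: int = 1000
    with_promoters: bool = True
    physio_noise_frac: float = 0.05

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class proportions sum to {total}, not 1")
        taus = list(self.cultivar_tau.values())
        if len(taus) < 2:
            raise ValidationError("need >= 2 cultivars")


@dataclass
class TruthRecord:
    """Ground truth of a simulated study."""

    tau: dict                 # cultivar -> tolerance coefficient in [0, 1]
    gene_class: dict          # gene -> regulatory class
    planted: dict             # gene -> list of (motif_name, start_position)
    effects: dict             # gene -> {treatment: true log2 effect size}

    def __post_init__(self) -> None:
        taus = list(self.tau.values())
        if taus.count(max(taus)) != 1 or taus.count(min(taus)) != 1:
            raise ValidationError("exactly one cultivar must attain max tau and one min tau")

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def truth_ranking(truth: TruthRecord) -> list[str]:
    """Cultivars by true tolerance, descending; ties broken by cultivar id."""
    if len(truth.tau) < 2:
        raise ValidationError("need >= 2 cultivars to rank")
    return sorted(truth.tau, key=lambda c: (-truth.tau[c], c))


def _attenuation(tau: float, treatment: str, floor: float) -> float:
    # tolerant cultivars maintain acute-shock induction; the ramp is mild
    # enough that all cultivars respond fully
    if treatment == "acute_50":
        return floor + (1.0 - floor) * tau
    return 1.0


def _assign_classes(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[list[str], dict]:
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    counts = {}
    remaining = cfg.n_genes
    for cls in GENE_CLASSES[:-1]:
        k = int(round(cfg.class_proportions.get(cls, 0.0) * cfg.n_genes))
        if cfg.class_proportions.get(cls, 0.0) > 0 and k == 0:
            raise ValidationError(f"n_genes={cfg.n_genes} too small to host class {cls}")
        counts[cls] = k
        remaining -= k
    if remaining < 0:
        raise ValidationError(f"n_genes={cfg.n_genes} too small to host all classes")
    counts["background"] = remaining
    perm = rng.permutation(cfg.n_genes)
    gene_class = {}
    pos = 0
    for cls in GENE_CLASSES:
        for i in perm[pos : pos + counts[cls]]:
            gene_class[genes[i]] = cls
        pos += counts[cls]
    return genes, gene_class


_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

_MOTIF_BASES = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT", "R": "AG", "K": "GT"}


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Draw a concrete site uniformly over a degenerate pattern's alphabet."""
    return "".join(
        b if b in "ACGT" else _MOTIF_BASES[b][rng.integers(len(_MOTIF_BASES[b]))]
        for b in pattern
    )


def _make_promoters(
    genes: list[str], gene_class: dict, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[PromoterSet, dict]:
    L = cfg.upstream_len
    raw = _ALPHABET[rng.integers(0, 4, size=(len(genes), L))]
    promoters: PromoterSet = {}
    planted: dict = {}
    for i, g in enumerate(genes):
        seq = bytes(raw[i]).decode()
        sites: list[tuple[str, int]] = []
        plan = _PLANT_PLAN.get(gene_class[g], ())
        occupied: list[tuple[int, int]] = []
        for motif_name in plan:
            pattern = MOTIF_REGISTRY[motif_name].pattern
            site = _instantiate(pattern, rng)
            m = len(site)
            for _ in range(1000):
                start = int(rng.integers(0, L - m + 1))
                if all(start + m <= a or start >= b for a, b in occupied):
                    break
            else:  # pragma: no cover - 1 kb always has room for a handful of sites
                raise ValidationError(f"could not place motif {motif_name} in {g}")
            occupied.append((start, start + m))
            seq = seq[:start] + site + seq[start + m :]
            sites.append((motif_name, start))
        promoters[g] = seq
        planted[g] = sites
    return promoters, planted


def simulate_study(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[ExpressionStudy, PromoterSet, pd.DataFrame, TruthRecord]:
    """Generate (expression, promoters, physiology, truth) for one seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    genes, gene_class = _assign_classes(cfg, rng)

    # per-gene realized effect sizes (log2), truncated at zero
    effects: dict = {}
    for g in genes:
        cls = gene_class[g]
        eff = {}
        for treatment in ("acute_50", "stepwise_40_50"):
            mean = (cfg.effect_acute if treatment == "acute_50" else cfg.effect_stepwise).get(cls, 0.0)
            eff[treatment] = float(max(0.0, rng.normal(mean, cfg.effect_sd))) if mean > 0 else 0.0
        eff["control_25"] = 0.0
        effects[g] = eff

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    samples: list[SampleInfo] = []
    columns: list[np.ndarray] = []
    delta = {
        t: np.array([effects[g][t] for g in genes]) for t in TREATMENT_TIMES
    }
    for cultivar, tau in cfg.cultivar_tau.items():
        for treatment, time_h in TREATMENT_TIMES.items():
            s = _attenuation(tau, treatment, cfg.attenuation_floor)
            mean_expr = baseline + delta[treatment] * s
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(
                    SampleInfo(
                        sample_id=f"{cultivar}_{treatment}_r{rep}",
                        cultivar=cultivar,
                        treatment=treatment,
                        time_h=time_h,
                        replicate=rep,
                    )
                )
                columns.append(mean_expr + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes))
    study = ExpressionStudy(genes=genes, samples=samples, values=np.column_stack(columns))

    promoters: PromoterSet = {}
    planted: dict = {g: [] for g in genes}
    if cfg.with_promoters:
        promoters, planted = _make_promoters(genes, gene_class, cfg, rng)

    physio = _make_physio(cfg, rng)

    truth = TruthRecord(tau=dict(cfg.cultivar_tau), gene_class=gene_class,
                        planted=planted, effects=effects)
    return study, promoters, physio, truth


def _make_physio(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Physiology degrades with 1 - tau: after/before ratios and LWI rise with tau."""
    rows = []
    for cultivar, tau in cfg.cultivar_tau.items():
        ratio = 0.35 + 0.6 * tau          # survival fraction of each parameter
        means = {
            "fvfm_before": 0.80,
            "fvfm_after": 0.80 * ratio,
            "root_wt_before_g": 0.50,
            "root_wt_after_g": 0.50 * ratio,
            "shoot_wt_before_g": 2.00,
            "shoot_wt_after_g": 2.00 * ratio,
            "lwi": min(1.1, 0.55 + 0.5 * tau),
        }
        for parameter, mean in means.items():
            sd = cfg.physio_noise_frac * mean
            for rep in range(1, cfg.n_physio_replicates + 1):
                rows.append(
                    {
                        "cultivar": cultivar,
                        "parameter": parameter,
                        "replicate": rep,
                        "value": float(max(0.0, rng.normal(mean, sd))),
                    }
                )
    return pd.DataFrame(rows)


def write_outputs(
    outdir: str | Path,
    study: ExpressionStudy,
    promoters: PromoterSet,
    physio: pd.DataFrame,
    truth: TruthRecord,
) -> None:
    """Write expression.tsv, samples.tsv, promoters.fasta, physiology.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_study(study, outdir / "expression.tsv", outdir / "samples.tsv")
    write_table(physio, outdir / "physiology.tsv")
    with open(outdir / "promoters.fasta", "w") as fh:
        for g, seq in promoters.items():
            fh.write(f">{g}\n{seq}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1)
    log.info("wrote synthetic study to %s", outdir)
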