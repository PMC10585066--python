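"""Expression-biomarker selection and cultivar thermotolerance scoring.

Candidate biomarkers are genes whose acute-heat response separates a
tolerant from a sensitive reference cultivar, selected by three strict
log2 criteria (defaults): induction in the tolerant cultivar > 6; tolerant
minus sensitive stress level > 1.4; absolute stress level in the tolerant
cultivar > 12.  Cultivars are then scored by the mean across the panel of
each gene's cross-cultivar z-score of stress-time expression — tolerant
cultivars keep biomarker expression high, so a high mean z indicates
thermotolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import InductionTable
from .io import ExpressionStudy, ValidationError, get_logger
from .physio import PhysioIndex

__all__ = ["BiomarkerPanel", "ScoreTable", "select_candidates", "score_cultivars", "concordance"]

log = get_logger("biomarker")


@dataclass
class BiomarkerPanel:
    """Per-candidate criterion values and the selected panel."""

    table: pd.DataFrame  # gene, induction_tolerant, ratio_tol_sen, level_tolerant,
                         # pass_induction, pass_ratio, pass_level, selected
    tolerant: str
    sensitive: str

    @property
    def genes(self) -> list:
        sel = self.table[self.table["selected"]]
        return list(sel["gene"])


def select_candidates(
    tab: InductionTable,
    tolerant: str,
    sensitive: str,
    induction_min_log2: float = 6.0,
    ratio_min_log2: float = 1.4,
    level_min_log2: float = 12.0,
    force_include: list | None = None,
) -> BiomarkerPanel:
    """Apply the three selection criteria (all strict inequalities).

    The panel is sorted by tolerant-cultivar induction descending with
    lexicographic tie-break; ``force_include`` adds named genes regardless
    of the criteria (appended after the criteria-selected genes).
    """
    tol = tab.for_cultivar(tolerant)
    sen = tab.for_cultivar(sensitive)
    genes = list(tab.genes)
    ind = tol["log2_induction"].reindex(genes)
    lvl_t = tol["stress_level"].reindex(genes)
    lvl_s = sen["stress_level"].reindex(genes)
    ratio = lvl_t - lvl_s

    df = pd.DataFrame(
        {
            "gene": genes,
            "induction_tolerant": ind.to_numpy(),
            "ratio_tol_sen": ratio.to_numpy(),
            "level_tolerant": lvl_t.to_numpy(),
        }
    )
    df["pass_induction"] = df["induction_tolerant"] > induction_min_log2
    df["pass_ratio"] = df["ratio_tol_sen"] > ratio_min_log2
    df["pass_level"] = df["level_tolerant"] > level_min_log2
    df["selected"] = df["pass_induction"] & df["pass_ratio"] & df["pass_level"]
    if force_include:
        unknown = set(force_include) - set(genes)
        if unknown:
            raise ValidationError(f"force_include gene(s) not in table: {sorted(unknown)}")
        df.loc[df["gene"].isin(force_include), "selected"] = True
    df = df.sort_values(
        ["selected", "induction_tolerant", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return BiomarkerPanel(table=df, tolerant=tolerant, sensitive=sensitive)


@dataclass
class ScoreTable:
    """Per-gene cross-cultivar z-scores and the per-cultivar mean over a panel."""

    gene_z: pd.DataFrame   # genes x cultivars
    mean_z: pd.Series      # cultivar -> mean z over panel
    ranking: list          # cultivars by mean z descending
    panel_size: int

    @property
    def most_tolerant(self) -> str:
        return self.ranking[0]

    @property
    def most_sensitive(self) -> str:
        return self.ranking[-1]


def score_cultivars(
    study: ExpressionStudy,
    panel: list,
    stress: tuple,
    ddof: int = 1,
) -> ScoreTable:
    """Score each cultivar by the mean cross-cultivar z of panel-gene expression.

    ``stress`` is a (treatment, time_h) selector with >= 2 replicates per
    cultivar.  Per gene, replicate-mean log2 expression per cultivar is
    z-scored across cultivars; genes with zero cross-cultivar variance are
    dropped with a warning.
    """
    if not panel:
        raise ValidationError("empty biomarker panel")
    cultivars = study.cultivars
    gidx = study.gene_index()
    missing = [g for g in panel if g not in gidx]
    if missing:
        raise ValidationError(f"panel gene(s) not in study: {missing[:5]}")
    rows = np.array([gidx[g] for g in panel])
    means = np.column_stack(
        [
            np.nanmean(study.replicate_values(c, stress[0], stress[1])[rows], axis=1)
            for c in cultivars
        ]
    )  # panel genes x cultivars
    sd = means.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(panel, keep) if not k]
        log.warning("dropping %d degenerate panel gene(s): %s", len(dropped), dropped[:5])
    if not keep.any():
        raise ValidationError("panel empty after dropping degenerate genes")
    z = (means[keep] - means[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    gene_z = pd.DataFrame(z, index=[g for g, k in zip(panel, keep) if k], columns=cultivars)
    mean_z = gene_z.mean(axis=0)
    ranking = sorted(mean_z.index, key=lambda c: (-mean_z[c], c))
    return ScoreTable(gene_z=gene_z, mean_z=mean_z, ranking=ranking, panel_size=int(keep.sum()))


def concordance(scores: ScoreTable, physio: PhysioIndex) -> float:
    """Spearman rank correlation between mean biomarker z and the composite
    physiological index over the shared cultivar set."""
    common = [c for c in scores.mean_z.index if c in physio.total.index]
    if len(common) < 3:
        raise ValidationError("need >= 3 shared cultivars for a rank correlation")
    rho = stats.spearmanr(
        scores.mean_z.loc[common].to_numpy(), physio.total.loc[common].to_numpy()
    ).statistic
    return float(rho)
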