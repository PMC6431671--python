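"""iTRAQ 4-plex reporter-ion quantification and differential-protein calling.

A 4-plex iTRAQ experiment labels one reference sample (channel 114) and
three case samples (channels 115-117) per batch.  Relative abundance of a
peptide in a case sample is the ratio of its reporter peak area to the
channel-114 area.  Protein-level ratios are the per-batch arithmetic mean
of the peptide ratios, normalized so that the bulk of the proteome is
centred at 1.0, and a protein is called differentially expressed (DEP)
when its mean ratio, significance, peptide support, identification score
and patient consensus all clear their thresholds.

Pipeline order is fixed: isotope correction -> peptide ratios -> protein
rollup -> within-batch normalization -> per-protein t-test -> DEP calling.
Row order of the input never affects any output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: reporter channels of a 4-plex experiment; 114 is the reference channel
CHANNELS = (114, 115, 116, 117)
CASE_CHANNELS = (115, 116, 117)

AREA_COLUMNS = [f"area_{c}" for c in CHANNELS]
RATIO_COLUMNS = [f"ratio_{c}" for c in CASE_CHANNELS]

#: schema of a peptide-spectrum table (one row per peptide x batch)
SPECTRA_SCHEMA = {
    "peptide_id": str,
    "protein_acc": str,
    "batch": int,
    "area_114": float,
    "area_115": float,
    "area_116": float,
    "area_117": float,
    "protein_score": float,
    "unused_score": float,
}


class ConfigurationError(ValueError):
    """Raised for invalid matrices, thresholds or empty required inputs."""


@dataclass(frozen=True)
class DepThresholds:
    """Cut-offs for calling a differentially expressed protein.

    A protein is called iff mean_ratio > ``up`` or < ``down`` (strict),
    p_value < ``alpha``, n_peptides >= ``min_peptides``, unused_score >
    ``min_unused_score`` and consensus_fraction > ``min_consensus``.
    Defaults follow the serum biomarker design: fold cuts 1.2/0.8,
    alpha 0.05, at least two peptides, unused score above 2 (99 %
    identification confidence) and more than 25 of 30 patients on the
    same side of 1.0 as the protein mean.
    """

    up: float = 1.2
    down: float = 0.8
    alpha: float = 0.05
    min_peptides: int = 2
    min_unused_score: float = 2.0
    min_consensus: float = 25.0 / 30.0

    def __post_init__(self) -> None:
        if not (self.down < 1.0 < self.up):
            raise ConfigurationError(
                f"fold thresholds must satisfy down < 1 < up, got "
                f"down={self.down}, up={self.up}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_peptides < 1:
            raise ConfigurationError("min_peptides must be >= 1")
        if not (0.0 <= self.min_consensus <= 1.0):
            raise ConfigurationError("min_consensus must lie in [0, 1]")


# ---------------------------------------------------------------------------
# isotope purity correction
# ---------------------------------------------------------------------------

def validate_purity_matrix(m: np.ndarray) -> np.ndarray:
    """Validate a 4x4 isotope purity matrix.

    Rows index the observed channel, columns the true channel; column j
    gives the fractions of tag j's signal observed in each channel, so
    every column must sum to 1 and the matrix must be well conditioned.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ConfigurationError(f"purity matrix must be 4x4, got shape {m.shape}")
    col_sums = m.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-6):
        raise ConfigurationError(
            f"purity matrix columns must sum to 1, got sums {col_sums}"
        )
    if np.linalg.cond(m) > 1e8:
        raise ConfigurationError("purity matrix is singular or ill-conditioned")
    return m


def load_purity_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited 4x4 purity matrix from a text file."""
    return validate_purity_matrix(np.loadtxt(path))


def correct_isotope_overlap(areas: np.ndarray, purity: np.ndarray) -> np.ndarray:
    """Undo isotopic channel cross-talk by solving ``purity @ true = observed``.

    ``areas`` is an (n, 4) array (or a single 4-vector) of observed reporter
    areas.  With an identity purity matrix the areas pass through unchanged.
    Corrected areas that come out negative (noise near the detection floor)
    are clipped to zero with a warning.
    """
    purity = validate_purity_matrix(purity)
    arr = np.atleast_2d(np.asarray(areas, dtype=float))
    if arr.shape[1] != 4:
        raise ValueError(f"expected 4 channel areas per row, got {arr.shape[1]}")
    corrected = np.linalg.solve(purity, arr.T).T
    n_neg = int((corrected < 0).sum())
    if n_neg:
        logger.warning("isotope correction clipped %d negative areas to 0", n_neg)
        corrected = np.clip(corrected, 0.0, None)
    return corrected[0] if np.ndim(areas) == 1 else corrected


def correct_spectra(spectra: pd.DataFrame, purity: np.ndarray) -> pd.DataFrame:
    """Apply isotope correction to the four area columns of a spectra table."""
    out = spectra.copy()
    out[AREA_COLUMNS] = correct_isotope_overlap(
        spectra[AREA_COLUMNS].to_numpy(float), purity
    )
    return out


# ---------------------------------------------------------------------------
# ratios, rollup, normalization
# ---------------------------------------------------------------------------

def compute_peptide_ratios(spectra: pd.DataFrame) -> pd.DataFrame:
    """Per-spectrum case/reference ratios (115/114, 116/114, 117/114).

    Spectra whose reference area (channel 114) is zero cannot form a ratio;
    they are excluded with a logged warning rather than aborting the run.
    """
    usable = spectra["area_114"] > 0
    n_bad = int((~usable).sum())
    if n_bad:
        logger.warning("excluded %d spectra with zero reference (114) area", n_bad)
    out = spectra.loc[usable].copy()
    ref = out["area_114"].to_numpy(float)
    for ch in CASE_CHANNELS:
        out[f"ratio_{ch}"] = out[f"area_{ch}"].to_numpy(float) / ref
    return out


def rollup_protein(ratios: pd.DataFrame) -> pd.DataFrame:
    """Average peptide ratios to one row per (protein, batch).

    Returns columns protein_acc, batch, ratio_115/116/117 (arithmetic means
    over the protein's peptides in that batch), n_peptides (distinct
    peptide_ids in the batch) and the protein's score metadata.
    """
    if ratios.empty:
        raise ConfigurationError("no usable spectra to roll up")
    grouped = ratios.groupby(["protein_acc", "batch"], sort=True)
    agg = grouped.agg(
        **{col: (col, "mean") for col in RATIO_COLUMNS},
        n_peptides=("peptide_id", "nunique"),
        protein_score=("protein_score", "max"),
        unused_score=("unused_score", "max"),
    ).reset_index()
    return agg


def normalize_ratios(rollup: pd.DataFrame, stat: str = "median") -> pd.DataFrame:
    """Normalize protein ratios by each channel's overall ratio within a batch.

    Divides every ratio column by the batch-wide aggregate (median by
    default; mean available) of that column, so that after normalization
    the overall ratio per channel equals 1 — this removes small differences
    in protein loading between channels.  Idempotent: normalizing an
    already-normalized batch changes nothing.
    """
    if rollup.empty:
        raise ConfigurationError("cannot normalize an empty batch")
    if stat not in ("median", "mean"):
        raise ConfigurationError(f"unknown normalization statistic {stat!r}")
    out = rollup.copy()
    for _, idx in out.groupby("batch").groups.items():
        block = out.loc[idx, RATIO_COLUMNS]
        overall = block.median(axis=0) if stat == "median" else block.mean(axis=0)
        if (overall <= 0).any():
            raise ConfigurationError("non-positive overall ratio; cannot normalize")
        out.loc[idx, RATIO_COLUMNS] = block / overall
    return out


def to_patient_ratios(rollup: pd.DataFrame) -> pd.DataFrame:
    """Reshape per-(protein, batch) channel ratios to one row per patient.

    A patient is a (batch, case-channel) pair; with 10 batches of 3 case
    channels this yields the 30-patient design.
    """
    long = rollup.melt(
        id_vars=["protein_acc", "batch"],
        value_vars=RATIO_COLUMNS,
        var_name="channel",
        value_name="ratio",
    )
    long["channel"] = long["channel"].str.removeprefix("ratio_").astype(int)
    return long.sort_values(["protein_acc", "batch", "channel"], ignore_index=True)


# ---------------------------------------------------------------------------
# testing and calling
# ---------------------------------------------------------------------------

def test_differential(ratios: np.ndarray) -> float:
    """Two-sided one-sample t-test of log2 ratios against 0.

    The control is the ratio denominator (its value is identically 1), so
    a two-sample test is degenerate; the one-sample test on log2 ratios
    asks whether the case/control fold change differs from 1.  Returns NaN
    (not testable) for fewer than two ratios or zero variance.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        return math.nan
    logs = np.log2(ratios)
    if np.allclose(logs, logs[0]):
        return math.nan
    return float(stats.ttest_1samp(logs, 0.0).pvalue)


def summarize_proteins(patient_ratios: pd.DataFrame,
                       meta: pd.DataFrame) -> pd.DataFrame:
    """Per-protein summary over all patients: mean ratio, p-value, consensus.

    ``meta`` carries per-protein n_peptides (distinct peptides over the whole
    experiment) and score metadata.  consensus_fraction is the fraction of
    patients whose individual ratio lies on the same side of 1.0 as the
    protein's mean ratio.
    """
    rows = []
    for acc, grp in patient_ratios.groupby("protein_acc", sort=True):
        r = grp["ratio"].to_numpy(float)
        mean_ratio = float(r.mean())
        if mean_ratio > 1.0:
            consensus = float((r > 1.0).mean())
        elif mean_ratio < 1.0:
            consensus = float((r < 1.0).mean())
        else:
            consensus = 0.0
        rows.append(
            {
                "protein_acc": acc,
                "mean_ratio": mean_ratio,
                "p_value": test_differential(r),
                "n_patients": len(r),
                "consensus_fraction": consensus,
            }
        )
    summary = pd.DataFrame(rows)
    return summary.merge(meta, on="protein_acc", how="left", validate="1:1")


def protein_meta(spectra: pd.DataFrame) -> pd.DataFrame:
    """Distinct-peptide counts and score metadata per protein."""
    return (
        spectra.groupby("protein_acc", sort=True)
        .agg(
            n_peptides=("peptide_id", "nunique"),
            protein_score=("protein_score", "max"),
            unused_score=("unused_score", "max"),
        )
        .reset_index()
    )


def call_deps(summary: pd.DataFrame,
              thresholds: DepThresholds | None = None) -> pd.DataFrame:
    """Call differentially expressed proteins from a protein summary table.

    Requires columns protein_acc, mean_ratio, p_value, n_peptides,
    unused_score, consensus_fraction.  All fold/score/consensus comparisons
    are strict; a mean ratio of exactly 1.2 or 0.8 is never called.  NaN
    p-values (untestable proteins) are excluded.  Output carries a
    direction column (up/down) and is sorted by |log2 mean_ratio|
    descending, ties broken by accession.
    """
    th = thresholds or DepThresholds()
    s = summary
    up = s["mean_ratio"] > th.up
    down = s["mean_ratio"] < th.down
    called = (
        (up | down)
        & (s["p_value"] < th.alpha)
        & s["p_value"].notna()
        & (s["n_peptides"] >= th.min_peptides)
        & (s["unused_score"] > th.min_unused_score)
        & (s["consensus_fraction"] > th.min_consensus)
    )
    deps = s.loc[called].copy()
    deps["direction"] = np.where(deps["mean_ratio"] > th.up, "up", "down")
    deps["abs_log2_ratio"] = np.abs(np.log2(deps["mean_ratio"]))
    deps = deps.sort_values(
        ["abs_log2_ratio", "protein_acc"], ascending=[False, True],
        ignore_index=True,
    )
    return deps.drop(columns="abs_log2_ratio")


def run_quant_pipeline(
    spectra: pd.DataFrame,
    purity: np.ndarray | None = None,
    thresholds: DepThresholds | None = None,
    norm_stat: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full quantification pipeline: spectra in, (summary, DEP table) out."""
    work = spectra.sort_values(
        ["protein_acc", "batch", "peptide_id"], ignore_index=True
    )
    if purity is not None:
        work = correct_spectra(work, purity)
    ratios = compute_peptide_ratios(work)
    rollup = normalize_ratios(rollup_protein(ratios), stat=norm_stat)
    summary = summarize_proteins(to_patient_ratios(rollup), protein_meta(ratios))
    return summary, call_deps(summary, thresholds)
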