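"""Cohort-level splice-variant survival study: model and results objects.

:class:`Nkp44SurvivalStudy` is built from a gene-level expression matrix,
an isoform-level matrix and a clinical table, and ``fit()`` runs the full
analysis chain:

1. peripheral-blood selection (TCGA sample-type 03) and optional
   participant de-duplication;
2. NKp46/NCR1 positivity filter;
3. splice-variant fractions and profile classification per sample;
4. median split of the NKp44-1 profile group on NKp44-1/NCR1;
5. Kaplan–Meier curves and pairwise log-rank tests among the profile
   groups, and again with the NKp44-1 group split into HIGH/LOW;
6. expression correlations (gene-level NCR2 vs summed isoforms; total
   NKp44 vs the NKp44-3/NKp44-1 ratio).

The returned :class:`Nkp44StudyResults` carries stage counts, the
per-sample classification table, the survival curves and test results,
and renders a plain-text ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import profiling, stats
from .profiling import ProfileLabel, SampleClassification, Subgroup
from .stats import KMCurve, LogRankResult, PearsonResult
from .tcga import (
    DEFAULT_ISOFORM_ALIASES,
    read_clinical,
    read_rsem_table,
    select_peripheral_blood,
    dedupe_participants,
)

__all__ = ["Nkp44SurvivalStudy", "Nkp44StudyResults", "ratio_correlation"]

_PROFILE_ORDER = (ProfileLabel.NKP44_1, ProfileLabel.NKP44_2_3, ProfileLabel.NKP44_NEG)


def ratio_correlation(
    classified: list[SampleClassification], which: str
) -> tuple[PearsonResult, int]:
    """Pearson correlation between total NKp44 expression and a second quantity.

    ``which="total_vs_gene"`` correlates the summed isoform expression with
    the gene-level NCR2 value (a near-identity when quantification is
    consistent). ``which="total_vs_f3f1"`` correlates total NKp44 with the
    NKp44-3/NKp44-1 ratio; samples with NKp44-1 = 0 have no ratio and are
    excluded. Returns the correlation and the number of excluded samples.
    """
    if which == "total_vs_gene":
        usable = [c for c in classified]
        x = [c.v1 + c.v2 + c.v3 for c in usable]
        y = [c.ncr2_total for c in usable]
        excluded = 0
    elif which == "total_vs_f3f1":
        usable = [c for c in classified if c.v1 > 0]
        excluded = len(classified) - len(usable)
        x = [c.v1 + c.v2 + c.v3 for c in usable]
        y = [c.v3 / c.v1 for c in usable]
    else:
        raise ValueError(f"unknown correlation {which!r}")
    if len(usable) < 3:
        raise ValueError(
            f"{which}: fewer than 3 usable samples ({len(usable)})"
        )
    return stats.pearson(x, y), excluded


class Nkp44SurvivalStudy:
    """Splice-variant profiling and survival model for one cohort.

    Parameters
    ----------
    gene_table, isoform_table : pandas.DataFrame
        Sample x feature matrices of RSEM-normalized values, indexed by
        TCGA-style barcode (as produced by
        :func:`nkp44var.tcga.read_rsem_table`).
    clinical : pandas.DataFrame
        days_to_event / event (/ risk_group) indexed by barcode.
    isoform_aliases : mapping, optional
        Isoform feature id -> {"NKp44-1", "NKp44-2", "NKp44-3"}.
    tau : float
        Positivity threshold applied to NCR1 and to each isoform
        (strictly-greater rule); 0 means any reported expression counts.
    events_only : bool
        Restrict the survival analysis to records with an observed death
        (the study's replicate mode); censored records are dropped with a
        count. False keeps censored records under the standard
        right-censoring treatment.
    dedupe : {"first", "last", None}
        Collapse multiple aliquots per participant, or keep all.
    """

    def __init__(
        self,
        gene_table: pd.DataFrame,
        isoform_table: pd.DataFrame,
        clinical: pd.DataFrame,
        *,
        isoform_aliases: dict[str, str] | None = None,
        tau: float = 0.0,
        events_only: bool = True,
        dedupe: str | None = "first",
    ) -> None:
        self.gene_table = gene_table
        self.isoform_table = isoform_table
        self.clinical = clinical
        self.aliases = dict(isoform_aliases or DEFAULT_ISOFORM_ALIASES)
        roles = set(self.aliases.values())
        needed = {"NKp44-1", "NKp44-2", "NKp44-3"}
        if not needed <= roles:
            raise ValueError(
                f"isoform alias map must cover {sorted(needed)}, got {sorted(roles)}"
            )
        self.tau = float(tau)
        self.events_only = bool(events_only)
        self.dedupe = dedupe

    # ------------------------------------------------------------------
    @classmethod
    def from_directory(
        cls, expression_dir: str | Path, clinical_path: str | Path | None = None, **kw
    ) -> "Nkp44SurvivalStudy":
        """Build from a directory of per-sample normalized_results files."""
        expression_dir = Path(expression_dir)
        gpaths = sorted(expression_dir.glob("*.rsem.genes.normalized_results"))
        ipaths = sorted(expression_dir.glob("*.rsem.isoforms.normalized_results"))
        if not gpaths or not ipaths:
            raise FileNotFoundError(
                f"no normalized_results files under {expression_dir}"
            )
        if clinical_path is None:
            clinical_path = expression_dir / "clinical.tsv"
        return cls(
            read_rsem_table(gpaths, "gene"),
            read_rsem_table(ipaths, "isoform"),
            read_clinical(clinical_path),
            **kw,
        )

    @classmethod
    def from_cohort(cls, cohort, **kw) -> "Nkp44SurvivalStudy":
        """Build directly from a :class:`nkp44var.synthetic.SyntheticCohort`."""
        return cls(cohort.gene_table, cohort.isoform_table, cohort.clinical, **kw)

    # ------------------------------------------------------------------
    def _isoform_value(self, barcode: str, role: str) -> float:
        ids = [i for i, r in self.aliases.items() if r == role]
        vals = [
            float(self.isoform_table.at[barcode, i])
            for i in ids
            if i in self.isoform_table.columns
        ]
        vals = [v for v in vals if not np.isnan(v)]
        if not vals:
            raise ValueError(
                f"sample {barcode}: no value for {role} "
                f"(alias ids {ids} absent or missing)"
            )
        return float(sum(vals))

    def fit(self) -> "Nkp44StudyResults":
        """Run the full analysis and return the results object."""
        barcodes = [str(b) for b in self.isoform_table.index]
        counts: dict[str, int] = {"input": len(barcodes)}

        pb = select_peripheral_blood(barcodes)
        counts["peripheral_blood"] = len(pb)
        if self.dedupe is not None:
            pb = dedupe_participants(pb, keep=self.dedupe)
        counts["deduplicated"] = len(pb)
        if not pb:
            raise RuntimeError("no samples remain after peripheral-blood selection")

        classified: list[SampleClassification] = []
        for bc in pb:
            if "NCR1" not in self.gene_table.columns or bc not in self.gene_table.index:
                raise ValueError(f"sample {bc}: gene-level NCR1 value unavailable")
            ncr1 = float(self.gene_table.at[bc, "NCR1"])
            v1 = self._isoform_value(bc, "NKp44-1")
            v2 = self._isoform_value(bc, "NKp44-2")
            v3 = self._isoform_value(bc, "NKp44-3")
            ncr2 = (
                float(self.gene_table.at[bc, "NCR2"])
                if "NCR2" in self.gene_table.columns
                else None
            )
            classified.append(
                profiling.classify_sample(
                    bc, ncr1, v1, v2, v3, ncr2_total=ncr2,
                    tau_ncr1=self.tau, tau_isoform=self.tau,
                )
            )

        nkp46_pos = [c for c in classified
                     if c.label is not ProfileLabel.EXCLUDED_NKP46_NEG]
        counts["nkp46_positive"] = len(nkp46_pos)
        nkp44_pos = [c for c in nkp46_pos if c.label is not ProfileLabel.NKP44_NEG]
        counts["nkp44_positive"] = len(nkp44_pos)

        # high/low split of the NKp44-1 profile group
        ones = [c for c in nkp46_pos if c.label is ProfileLabel.NKP44_1]
        split = profiling.split_high_low(ones) if ones else []
        by_bc = {c.barcode: c for c in nkp46_pos}
        by_bc.update({c.barcode: c for c in split})
        classified = [by_bc.get(c.barcode, c) for c in classified]
        nkp46_pos = [by_bc[c.barcode] for c in nkp46_pos]

        # survival records
        matched, n_no_clinical, n_censored_dropped = {}, 0, 0
        for c in nkp46_pos:
            if c.barcode not in self.clinical.index:
                n_no_clinical += 1
                continue
            row = self.clinical.loc[c.barcode]
            event = bool(row["event"])
            if self.events_only and not event:
                n_censored_dropped += 1
                continue
            matched[c.barcode] = (float(row["days_to_event"]), event)
        if n_no_clinical:
            warnings.warn(
                f"{n_no_clinical} classified sample(s) had no clinical record; "
                "excluded from the survival comparison",
                stacklevel=2,
            )
        counts["with_survival_data"] = len(matched)
        counts["no_clinical_record"] = n_no_clinical
        counts["censored_dropped"] = n_censored_dropped

        def _records(members):
            t = [matched[c.barcode][0] for c in members if c.barcode in matched]
            e = [matched[c.barcode][1] for c in members if c.barcode in matched]
            return np.asarray(t, float), np.asarray(e, bool)

        profile_groups = {
            lab.value: _records([c for c in nkp46_pos if c.label is lab])
            for lab in _PROFILE_ORDER
        }
        subgroup_groups = {
            "NKP44_1_HIGH": _records(
                [c for c in nkp46_pos if c.subgroup is Subgroup.HIGH]
            ),
            "NKP44_1_LOW": _records(
                [c for c in nkp46_pos if c.subgroup is Subgroup.LOW]
            ),
            ProfileLabel.NKP44_2_3.value: profile_groups[ProfileLabel.NKP44_2_3.value],
            ProfileLabel.NKP44_NEG.value: profile_groups[ProfileLabel.NKP44_NEG.value],
        }

        km_curves = {
            name: stats.km_estimate(t, e)
            for name, (t, e) in {**profile_groups, **subgroup_groups}.items()
            if t.size and e.any()
        }
        logrank_profiles = self._pairwise(profile_groups)
        logrank_subgroups = self._pairwise(subgroup_groups)

        overall = None
        usable = {k: v for k, v in profile_groups.items() if v[0].size and v[1].any()}
        if len(usable) >= 2:
            overall = stats.logrank_test(
                [v[0] for v in usable.values()],
                [v[1] for v in usable.values()],
                labels=list(usable),
            )

        corr_gene = corr_ratio = None
        corr_ratio_excluded = 0
        if len(nkp44_pos) >= 3:
            try:
                corr_gene, _ = ratio_correlation(nkp44_pos, "total_vs_gene")
            except ValueError:
                corr_gene = None
            try:
                corr_ratio, corr_ratio_excluded = ratio_correlation(
                    nkp44_pos, "total_vs_f3f1"
                )
            except ValueError:
                corr_ratio = None

        return Nkp44StudyResults(
            model=self,
            stage_counts=counts,
            classified=classified,
            km_curves=km_curves,
            logrank_overall=overall,
            logrank_profiles=logrank_profiles,
            logrank_subgroups=logrank_subgroups,
            corr_total_vs_gene=corr_gene,
            corr_total_vs_f3f1=corr_ratio,
            corr_ratio_excluded=corr_ratio_excluded,
        )

    @staticmethod
    def _pairwise(groups: dict) -> pd.DataFrame:
        rows = []
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                (ta, ea), (tb, eb) = groups[a], groups[b]
                row = {"group_a": a, "group_b": b,
                       "n_a": int(ta.size), "n_b": int(tb.size)}
                if ta.size and tb.size and (ea.any() or eb.any()):
                    res = stats.logrank_test([ta, tb], [ea, eb], labels=[a, b])
                    row.update(chi_square=res.chi_square, p_value=res.p_value)
                else:
                    row.update(chi_square=np.nan, p_value=np.nan)
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class Nkp44StudyResults:
    """Fitted study: stage counts, classifications, curves and tests."""

    model: Nkp44SurvivalStudy
    stage_counts: dict[str, int]
    classified: list[SampleClassification]
    km_curves: dict[str, KMCurve]
    logrank_overall: LogRankResult | None
    logrank_profiles: pd.DataFrame
    logrank_subgroups: pd.DataFrame
    corr_total_vs_gene: PearsonResult | None
    corr_total_vs_f3f1: PearsonResult | None
    corr_ratio_excluded: int = 0

    # ------------------------------------------------------------------
    @property
    def classification(self) -> pd.DataFrame:
        """Per-sample classification table (TSV-ready)."""
        return profiling.classification_frame(self.classified)

    @property
    def group_sizes(self) -> pd.Series:
        return self.classification["label"].value_counts()

    @property
    def nkp44_positive_share(self) -> float:
        """Percent of NKp44+ profiles among NKp46+ samples (whole percent)."""
        labels = self.classification["label"]
        pos = int((labels.isin([ProfileLabel.NKP44_1.value,
                                ProfileLabel.NKP44_2_3.value])).sum())
        total = int((labels != ProfileLabel.EXCLUDED_NKP46_NEG.value).sum())
        return profiling.positive_share(pos, total)

    def profile_summary(self) -> pd.DataFrame:
        return profiling.cohort_summary(self.classified)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Readable multi-section report of the fitted study."""
        lines = ["NKp44 splice-variant survival study", "=" * 37, ""]
        lines.append("Filter chain (samples in -> out):")
        for stage, n in self.stage_counts.items():
            lines.append(f"  {stage:<22s} {n}")
        lines.append("")
        lines.append("Profile groups:")
        summ = self.profile_summary()
        for label, row in summ.iterrows():
            if row["n"]:
                lines.append(
                    f"  {label:<20s} n={int(row['n']):<4d} "
                    f"mean %variants (1/2/3) = "
                    f"{row['mean_f1']:.1f}/{row['mean_f2']:.1f}/{row['mean_f3']:.1f}"
                    if np.isfinite(row["mean_f1"])
                    else f"  {label:<20s} n={int(row['n']):<4d} fractions undefined"
                )
            else:
                lines.append(f"  {label:<20s} n=0")
        lines.append(
            f"  NKp44+ share of NKp46+ samples: {self.nkp44_positive_share:.0f}%"
        )
        lines.append("")
        if self.logrank_overall is not None:
            o = self.logrank_overall
            lines.append(
                f"Overall log-rank (Mantel-Cox): chi2={o.chi_square:.3f} "
                f"df={o.df} p={o.p_value:.4g}"
            )
        for title, table in (
            ("Pairwise log-rank, profile groups:", self.logrank_profiles),
            ("Pairwise log-rank, NKp44-1 high/low split:", self.logrank_subgroups),
        ):
            lines.append(title)
            for _, r in table.iterrows():
                p = "NA" if not np.isfinite(r["p_value"]) else f"{r['p_value']:.4g}"
                lines.append(
                    f"  {r['group_a']:<14s} vs {r['group_b']:<14s} "
                    f"(n={r['n_a']}/{r['n_b']})  p={p}"
                )
            lines.append("")
        if self.corr_total_vs_gene is not None:
            c = self.corr_total_vs_gene
            lines.append(
                f"Corr. summed isoforms vs gene-level NCR2: "
                f"r={c.r:.4f} p={c.p_value:.4g} n={c.n}"
            )
        if self.corr_total_vs_f3f1 is not None:
            c = self.corr_total_vs_f3f1
            lines.append(
                f"Corr. total NKp44 vs NKp44-3/NKp44-1 ratio: "
                f"r={c.r:.4f} p={c.p_value:.4g} n={c.n} "
                f"(excluded {self.corr_ratio_excluded} with undefined ratio)"
            )
        return "\n".join(lines)

    def to_tsv(self, directory: str | Path) -> list[Path]:
        """Write classification, KM-curve and test tables under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        p = directory / "classified.tsv"
        self.classification.to_csv(p, sep="\t", index=False)
        written.append(p)
        for name, curve in self.km_curves.items():
            p = directory / f"km_{name}.tsv"
            curve.to_frame().to_csv(p, sep="\t", index=False)
            written.append(p)
        p = directory / "logrank_profiles.tsv"
        self.logrank_profiles.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = directory / "logrank_subgroups.tsv"
        self.logrank_subgroups.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = directory / "report.txt"
        p.write_text(self.summary() + "\n")
        written.append(p)
        return written
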