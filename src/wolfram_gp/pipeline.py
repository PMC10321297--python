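"""End-to-end analysis: read → classify → annotate → group → test → report.

Produces, for a registry and a TM-domain table: cohort-level onset
summaries per manifestation; NSFS-dose comparison tables with pairwise
raw and Bonferroni-adjusted p-values; TM-dose tables for the two-in-frame
and one-in-frame genotype subsets; sex-stratified comparisons; optional
box-plot figures; and a JSON run manifest recording configuration, input
checksums and every exclusion with its reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cohort import (
    Exclusion,
    Manifestation,
    filter_eligible,
    read_registry,
)
from .domains import DomainTable, load_domain_table
from .stats import (
    GroupComparison,
    Grouping,
    compare_dose_groups,
    sex_stratified_comparison,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_analysis"]

_FLOAT_FMT = "{:.4f}"  # four decimals keep interpolated quartiles representable

_MANIFESTATION_NAMES = {
    Manifestation.DM: "Diabetes Mellitus",
    Manifestation.OA: "Optic Atrophy",
    Manifestation.DI: "Diabetes Insipidus",
    Manifestation.HL: "Hearing Loss",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one analysis run; flags win over config-file keys."""

    registry_path: str
    domain_table_path: str
    output_dir: str
    quartile_method: str = "linear"
    alpha: float = 0.05
    sidedness: str = "two_sided"
    figures: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.sidedness != "two_sided":
            raise ValueError("only two-sided tests are supported")


@dataclass
class ReportBundle:
    """In-memory results plus the paths of every table written."""

    cohort_summaries: dict[Manifestation, object]
    comparisons: dict[tuple[Manifestation, Grouping], GroupComparison]
    sex_comparisons: dict[Manifestation, GroupComparison]
    exclusions: dict[Manifestation, list[Exclusion]]
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fmt(value: float) -> str:
    return _FLOAT_FMT.format(value)


def _summary_rows(manifestation, grouping_name, comparison) -> list[str]:
    rows = []
    for label, s in comparison.per_group.items():
        rows.append(
            "\t".join(
                [
                    _MANIFESTATION_NAMES[manifestation],
                    grouping_name,
                    label,
                    str(s.n),
                    _fmt(s.median),
                    _fmt(s.q1),
                    _fmt(s.q3),
                    _fmt(s.whisker_low),
                    _fmt(s.whisker_high),
                    ";".join(_fmt(o) for o in s.outliers),
                ]
            )
        )
    return rows


def _pairwise_rows(manifestation, grouping_name, comparison) -> list[str]:
    rows = []
    for t in comparison.pairwise:
        rows.append(
            "\t".join(
                [
                    _MANIFESTATION_NAMES[manifestation],
                    grouping_name,
                    t.group_a,
                    t.group_b,
                    _fmt(t.u_statistic),
                    _fmt(t.p_raw),
                    _fmt(t.p_adjusted),
                ]
            )
        )
    if not comparison.testable:
        rows.append(
            "\t".join(
                [_MANIFESTATION_NAMES[manifestation], grouping_name,
                 "-", "-", "", "", "not testable"]
            )
        )
    return rows


_SUMMARY_HEADER = (
    "manifestation\tgrouping\tgroup\tn\tmedian\tlower_quartile\tupper_quartile"
    "\twhisker_low\twhisker_high\toutliers"
)
_PAIRWISE_HEADER = "manifestation\tgrouping\tgroup_a\tgroup_b\tU\tp_raw\tp_adjusted"


def _write_boxplots(out_dir: Path, bundle: ReportBundle) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for (manif, grouping), comp in bundle.comparisons.items():
        if not comp.per_group:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        labels = list(comp.per_group)
        stats_list = [
            {
                "label": label,
                "med": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whislo": s.whisker_low,
                "whishi": s.whisker_high,
                "fliers": list(s.outliers),
            }
            for label, s in comp.per_group.items()
        ]
        ax.bxp(stats_list, showfliers=True)
        ax.set_xticklabels(
            [f"{lab}\n(n={comp.per_group[lab].n})" for lab in labels], fontsize=8
        )
        ax.set_ylabel("age of onset (years)")
        ax.set_title(f"{_MANIFESTATION_NAMES[manif]} by {grouping.value}", fontsize=9)
        fig.tight_layout()
        path = out_dir / f"boxplot_{manif.value.lower()}_{grouping.value}.svg"
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths


def run_analysis(config: RunConfig) -> ReportBundle:
    """Run the full genotype–phenotype analysis and write the report bundle.

    Writes under ``config.output_dir``: ``cohort_summary.tsv`` (whole-cohort
    onset box statistics per manifestation), ``group_summaries.tsv`` and
    ``pairwise_tests.tsv`` (NSFS-dose, TM-dose and sex groupings), a
    ``manifest.json`` with config, input SHA-256 checksums and per-patient
    exclusion reasons, and (optionally) SVG box plots.  Deterministic:
    identical inputs yield byte-identical tables.
    """
    registry_path = Path(config.registry_path)
    domains_path = Path(config.domain_table_path)
    for p in (registry_path, domains_path):
        if not p.exists():
            raise FileNotFoundError(
                f"input {p} does not exist; check --registry/--domains paths"
            )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_registry(registry_path)
    domains: DomainTable = load_domain_table(domains_path)

    cohort_summaries: dict[Manifestation, object] = {}
    comparisons: dict[tuple[Manifestation, Grouping], GroupComparison] = {}
    sex_comparisons: dict[Manifestation, GroupComparison] = {}
    exclusions: dict[Manifestation, list[Exclusion]] = {}

    from .stats import five_number_summary  # local import avoids cycle at module load

    for manif in Manifestation:
        excl: list[Exclusion] = []
        eligible = filter_eligible(cohort, manif, domains=domains, exclusions=excl)
        exclusions[manif] = excl
        if eligible:
            cohort_summaries[manif] = five_number_summary(
                [p.onset_age for p in eligible], method=config.quartile_method
            )
        for grouping in (
            Grouping.NSFS_DOSE,
            Grouping.TM_DOSE_TWO_INFRAME,
            Grouping.TM_DOSE_ONE_INFRAME,
        ):
            comparisons[(manif, grouping)] = compare_dose_groups(
                eligible, manif, grouping, quartile_method=config.quartile_method
            )
        sex_comparisons[manif] = sex_stratified_comparison(
            eligible, manif, quartile_method=config.quartile_method
        )

    # --- tables -------------------------------------------------------------
    cohort_lines = ["manifestation\tn\tmedian\tlower_quartile\tupper_quartile"]
    for manif, s in cohort_summaries.items():
        cohort_lines.append(
            "\t".join(
                [_MANIFESTATION_NAMES[manif], str(s.n), _fmt(s.median),
                 _fmt(s.q1), _fmt(s.q3)]
            )
        )

    summary_lines, pairwise_lines = [_SUMMARY_HEADER], [_PAIRWISE_HEADER]
    for (manif, grouping), comp in comparisons.items():
        summary_lines += _summary_rows(manif, grouping.value, comp)
        pairwise_lines += _pairwise_rows(manif, grouping.value, comp)
    for manif, comp in sex_comparisons.items():
        summary_lines += _summary_rows(manif, "sex", comp)
        pairwise_lines += _pairwise_rows(manif, "sex", comp)

    paths = {
        "cohort_summary": out_dir / "cohort_summary.tsv",
        "group_summaries": out_dir / "group_summaries.tsv",
        "pairwise_tests": out_dir / "pairwise_tests.tsv",
        "manifest": out_dir / "manifest.json",
    }
    paths["cohort_summary"].write_text("\n".join(cohort_lines) + "\n")
    paths["group_summaries"].write_text("\n".join(summary_lines) + "\n")
    paths["pairwise_tests"].write_text("\n".join(pairwise_lines) + "\n")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            "registry": {"path": str(registry_path), "sha256": _sha256(registry_path)},
            "domain_table": {
                "path": str(domains_path),
                "sha256": _sha256(domains_path),
                "protein_id": domains.protein_id,
                "provenance": domains.provenance,
            },
        },
        "cohort_size": len(cohort),
        "eligible_n": {
            m.value: len(cohort) - len(exclusions[m]) for m in Manifestation
        },
        "exclusions": {
            m.value: [
                {"patient_id": e.patient_id, "reason": e.reason} for e in exclusions[m]
            ]
            for m in Manifestation
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    bundle = ReportBundle(
        cohort_summaries=cohort_summaries,
        comparisons=comparisons,
        sex_comparisons=sex_comparisons,
        exclusions=exclusions,
        manifest=manifest,
        paths=paths,
    )
    if config.figures:
        for fig_path in _write_boxplots(out_dir, bundle):
            bundle.paths[fig_path.stem] = fig_path
    return bundle
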