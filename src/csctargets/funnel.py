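"""Staged prioritization of antibody-accessible CSC surface targets.

The funnel reduces a differential-expression gene list to a ranked shortlist
in five nested stages:

1. genes significantly up-regulated in stem-phenotype CSCs versus their
   differentiated counterparts (pfp <= cutoff),
2. genes encoding transmembrane or GPI-anchored proteins,
3. genes consistently up-regulated in CSCs relative to every configured
   comparison class (normal colon, tumor, LCM variants, cell lines),
4. a rule-based rating (YES / MAYBE / NO) from fold change, vital-tissue
   expression, shedding and existing knowledge, with a target (T) versus
   biomarker (B) category,
5. removal of NO-rated genes and of genes failing immunogenicity, ectopic
   expression or paralog-similarity screens, ranked YES-first then by rank
   product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from .core import ConfigError, DataError, ExpressionStudy
from .rankprod import DEResult, class_fold_changes, pfp_filter, rank_product

__all__ = [
    "MEMBRANE_STATUSES",
    "VITAL_ORGANS",
    "FunnelConfig",
    "FunnelStage",
    "FunnelReport",
    "stage1_deg",
    "stage2_membrane",
    "stage3_consistency",
    "stage4_score",
    "stage5_final",
    "run_funnel",
    "validate_annotation",
]

MEMBRANE_STATUSES = ("transmembrane", "GPI", "none")
VITAL_ORGANS = ("brain", "heart", "lung", "liver", "kidney")
EXPRESSION_LEVELS = ("low", "medium", "high")
SHEDDING_LEVELS = ("limited", "extensive", "unknown")
KNOWLEDGE_LEVELS = ("favorable", "neutral", "unfavorable")

ANNOTATION_COLUMNS = (
    "membrane_status",
    *(f"vital_{o}" for o in VITAL_ORGANS),
    "shedding",
    "knowledge_score",
    "immunogenicity_ok",
    "ectopic_expression_ok",
    "paralog_similarity_ok",
)


def validate_annotation(annotation: pd.DataFrame, genes=None) -> None:
    missing_cols = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing_cols:
        raise DataError(f"annotation missing columns: {sorted(missing_cols)}")
    if genes is not None:
        missing = set(genes) - set(annotation.index)
        if missing:
            raise DataError(f"annotation missing genes: {sorted(missing)[:5]} ...")
    bad = set(annotation["membrane_status"]) - set(MEMBRANE_STATUSES)
    if bad:
        raise DataError(f"unknown membrane status values: {sorted(bad)}")


@dataclass
class FunnelConfig:
    """Cutoffs and class comparisons driving the funnel."""

    pfp_cutoff: float = 0.1
    fc_min: float = 2.0  # linear fold-change threshold, applied inclusively
    csc_class: str = "sCSC"
    differentiated_class: str = "dCSC"
    consistency_classes: tuple[str, ...] = ("normal", "tumor")
    fc_classes: tuple[str, ...] = ("tumor", "cell_line")  # stage-4 fold-change comparisons
    n_perm: int = 100
    max_pairs: int = 200
    seed: int | None = 0
    overrides: tuple[str, ...] = ()  # genes carried forward regardless of rating

    @classmethod
    def from_yaml(cls, path) -> "FunnelConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("consistency_classes", "fc_classes", "overrides"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class FunnelStage:
    name: str
    n_input: int
    survivors: list[str]

    @property
    def count(self) -> int:
        return len(self.survivors)


@dataclass
class FunnelReport:
    stages: list[FunnelStage] = field(default_factory=list)
    ratings: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    final_ranked: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_input: int, survivors) -> None:
        survivors = list(survivors)
        if self.stages and not set(survivors) <= set(self.stages[-1].survivors):
            raise DataError(f"stage {name!r} survivors are not nested in the previous stage")
        self.stages.append(FunnelStage(name, n_input, survivors))

    @property
    def counts(self) -> dict[str, int]:
        return {s.name: s.count for s in self.stages}

    def to_json(self, path=None) -> str:
        payload = {
            "stages": [
                {"name": s.name, "n_input": s.n_input, "count": s.count, "survivors": s.survivors}
                for s in self.stages
            ],
            "ratings": self.ratings,
            "categories": self.categories,
            "final_ranked": self.final_ranked,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def stage_tsv(self, path) -> None:
        rows = []
        for s in self.stages:
            for g in s.survivors:
                rows.append({"stage": s.name, "gene": g})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def stage1_deg(de: DEResult, cutoff: float = 0.1) -> list[str]:
    """Genes significantly up-regulated in stem versus differentiated CSCs."""
    return pfp_filter(de, cutoff=cutoff, direction="up")


def stage2_membrane(genes, annotation: pd.DataFrame) -> list[str]:
    """Keep genes annotated as transmembrane or GPI-anchored."""
    genes = list(genes)
    validate_annotation(annotation, genes)
    status = annotation.loc[genes, "membrane_status"]
    return [g for g in genes if status[g] in ("transmembrane", "GPI")]


def stage3_consistency(
    genes, de_by_class: dict[str, DEResult], cutoff: float = 0.1
) -> list[str]:
    """Keep genes up-regulated (pfp <= cutoff and positive fold change) in the
    CSC-versus-class comparison for every required class."""
    if not de_by_class:
        raise ConfigError("stage 3 needs at least one class comparison")
    genes = list(genes)
    survivors = []
    for g in genes:
        ok = True
        for cls, de in de_by_class.items():
            if g not in de.table.index:
                raise ConfigError(f"gene {g!r} missing from comparison vs {cls!r}")
            row = de.table.loc[g]
            if not (row["pfp_up"] <= cutoff and row["log2fc"] > 0):
                ok = False
                break
        if ok:
            survivors.append(g)
    return survivors


def _criteria(gene: str, fc_table: pd.DataFrame, annotation: pd.DataFrame,
              fc_classes, fc_min: float) -> dict:
    ann = annotation.loc[gene]
    fcs = []
    for cls in fc_classes:
        col = f"fc_{cls}"
        if col not in fc_table.columns or gene not in fc_table.index:
            raise DataError(f"missing fold-change entry for gene {gene!r} vs {cls!r}")
        fcs.append(float(fc_table.loc[gene, col]))
    organ_levels = [ann[f"vital_{o}"] for o in VITAL_ORGANS]
    return {
        "fc_ok": all(fc >= fc_min for fc in fcs),
        "fc_fail": any(fc < fc_min for fc in fcs),
        "organ_ok": all(l == "low" for l in organ_levels),
        "organ_fail": any(l == "high" for l in organ_levels),
        "shed_ok": ann["shedding"] == "limited",
        "shed_fail": ann["shedding"] == "extensive",
        "knowledge_ok": ann["knowledge_score"] == "favorable",
        "knowledge_fail": ann["knowledge_score"] == "unfavorable",
    }


def stage4_score(
    genes,
    fc_table: pd.DataFrame,
    annotation: pd.DataFrame,
    fc_min: float = 2.0,
    fc_classes=("tumor", "cell_line"),
) -> tuple[dict[str, str], dict[str, str]]:
    """Rate each gene YES / MAYBE / NO and assign a T/B category.

    NO when any criterion fails outright (fold change below ``fc_min`` vs any
    comparison class, a vital organ at high expression, extensive shedding, or
    unfavorable knowledge); YES when all four criteria are favorable; MAYBE
    otherwise.  Genes whose only shortfall is vital-tissue expression are
    categorized B (biomarker); everything else is T (therapeutic target).
    """
    genes = list(genes)
    validate_annotation(annotation, genes)
    ratings: dict[str, str] = {}
    categories: dict[str, str] = {}
    for g in genes:
        c = _criteria(g, fc_table, annotation, fc_classes, fc_min)
        if c["fc_fail"] or c["organ_fail"] or c["shed_fail"] or c["knowledge_fail"]:
            ratings[g] = "NO"
        elif c["fc_ok"] and c["organ_ok"] and c["shed_ok"] and c["knowledge_ok"]:
            ratings[g] = "YES"
        else:
            ratings[g] = "MAYBE"
        only_organ = (not c["organ_ok"]) and c["fc_ok"] and c["shed_ok"] and c["knowledge_ok"]
        categories[g] = "B" if only_organ else "T"
    return ratings, categories


def stage5_final(
    genes_rated: dict[str, str],
    annotation: pd.DataFrame,
    de_csc: DEResult,
    overrides=(),
) -> list[str]:
    """Drop NO-rated genes and genes failing the immunogenicity, ectopic
    expression or paralog-similarity screens; rank YES before MAYBE, then by
    ascending rank product versus the differentiated class.  ``overrides``
    names genes carried forward regardless of rating (the shortlist may keep
    genes on judgment calls the rules cannot express)."""
    validate_annotation(annotation, genes_rated)
    keep = []
    for g, rating in genes_rated.items():
        if rating == "NO" and g not in overrides:
            continue
        ann = annotation.loc[g]
        if not (
            bool(ann["immunogenicity_ok"])
            and bool(ann["ectopic_expression_ok"])
            and bool(ann["paralog_similarity_ok"])
        ):
            continue
        keep.append(g)
    rp = de_csc.table["RP_up"]
    return sorted(
        keep, key=lambda g: (0 if genes_rated[g] == "YES" else 1, rp.get(g, float("inf")), g)
    )


def run_funnel(
    study: ExpressionStudy,
    annotation: pd.DataFrame,
    config: FunnelConfig | None = None,
) -> FunnelReport:
    """Execute stages 1–5 on an integrated study and return the stage report."""
    config = config or FunnelConfig()
    validate_annotation(annotation, study.probe_ids)
    report = FunnelReport()
    n_genes = len(study.probe_ids)

    de_csc = rank_product(
        study,
        config.csc_class,
        config.differentiated_class,
        n_perm=config.n_perm,
        max_pairs=config.max_pairs,
        seed=config.seed,
    )
    s1 = stage1_deg(de_csc, cutoff=config.pfp_cutoff)
    report.add_stage("deg_up_csc", n_genes, s1)

    s2 = stage2_membrane(s1, annotation)
    report.add_stage("membrane", len(s1), s2)

    de_by_class = {}
    for i, cls in enumerate(config.consistency_classes):
        seed = None if config.seed is None else config.seed + 1000 * (i + 1)
        de_by_class[cls] = rank_product(
            study,
            config.csc_class,
            cls,
            n_perm=config.n_perm,
            max_pairs=config.max_pairs,
            seed=seed,
        )
    s3 = stage3_consistency(s2, de_by_class, cutoff=config.pfp_cutoff)
    report.add_stage("consistency", len(s2), s3)

    fc_table = class_fold_changes(study, config.csc_class, list(config.fc_classes))
    ratings, categories = stage4_score(
        s3, fc_table, annotation, fc_min=config.fc_min, fc_classes=config.fc_classes
    )
    s4 = [g for g in s3 if ratings[g] != "NO" or g in config.overrides]
    report.add_stage("scored", len(s3), s4)
    report.ratings = ratings
    report.categories = categories

    final = stage5_final(
        {g: ratings[g] for g in s4}, annotation, de_csc, overrides=config.overrides
    )
    report.add_stage("final", len(s4), final)
    report.final_ranked = final
    return report
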