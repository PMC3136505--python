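"""End-to-end orchestration: per-group gene analyses and the clade report.

A run analyzes each clade group separately (the groups' phylogenetic
inter-relationships need not be assumed), gene by gene: read the codon
alignment and group tree, reconstruct ancestral codons by parsimony,
enumerate nonsynonymous replacements, score property/category z-scores
against the neutral neighborhood expectation, classify selection calls, and
compute whole-protein sums.  The comparison stage then intersects each
group's positive-destabilizing site sets per property on the shared master
alignment coordinate system.

Genes are processed in sorted order and all intermediates are written as
TSV, so identical inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ancestral import enumerate_replacements, fitch_reconstruct, write_events_tsv
from .comparison import (
    DEFAULT_GROUPINGS,
    GroupComparison,
    collect_calls,
    intersect_groups,
    merge_call_sets,
)
from .errors import ConfigError, FrameError, PropselError
from .genetic_code import build_neighborhood, get_code
from .io import load_default_properties, read_codon_alignment, read_property_table, read_tree
from .property_model import DESTABILIZING_CATEGORIES, NullModel
from .selection import (
    DEFAULT_Z_THRESHOLD,
    classify,
    classify_band,
    site_zscore_arrays,
    site_profiles,
    whole_protein_from_arrays,
    write_calls_tsv,
    write_tests_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneInputs:
    name: str
    paths: dict[str, dict[str, str]]  # group -> {"alignment": ..., "tree": ...}


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    genes: list[GeneInputs]
    output: Path
    properties_path: str | None = None  # None -> bundled default table
    genetic_code: str = "vertebrate_mitochondrial"
    z_threshold: float = DEFAULT_Z_THRESHOLD
    window: int = 1
    categories: tuple[int, ...] = DESTABILIZING_CATEGORIES
    groupings: tuple[tuple[str, ...], ...] = DEFAULT_GROUPINGS
    #: 'band' pools the focus categories into one test per (site, property);
    #: 'category' emits per-category calls.
    site_statistic: str = "band"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        try:
            genes = [
                GeneInputs(name=g["name"], paths=g["groups"]) for g in raw["genes"]
            ]
            config = cls(
                genes=genes,
                output=Path(raw["output"]),
                properties_path=raw.get("properties"),
                genetic_code=raw.get("genetic_code", "vertebrate_mitochondrial"),
                z_threshold=float(raw.get("z_threshold", DEFAULT_Z_THRESHOLD)),
                window=int(raw.get("window", 1)),
                categories=tuple(raw.get("categories", DESTABILIZING_CATEGORIES)),
                groupings=tuple(
                    tuple(g) for g in raw.get("groupings", DEFAULT_GROUPINGS)
                ),
                site_statistic=raw.get("site_statistic", "band"),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc
        config.validate()
        return config

    def validate(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be > 0")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if self.site_statistic not in ("band", "category"):
            raise ConfigError("site_statistic must be 'band' or 'category'")
        if not self.genes:
            raise ConfigError("no genes configured")
        for gene in self.genes:
            for group, paths in gene.paths.items():
                for key in ("alignment", "tree"):
                    if key not in paths:
                        raise ConfigError(f"gene {gene.name}/{group}: missing {key}")
                    if not Path(paths[key]).exists():
                        raise ConfigError(
                            f"gene {gene.name}/{group}: {key} path does not exist: "
                            f"{paths[key]}"
                        )
        if self.properties_path is not None and not Path(self.properties_path).exists():
            raise ConfigError(f"property table not found: {self.properties_path}")

    def load_null_model(self) -> NullModel:
        table = (
            load_default_properties()
            if self.properties_path is None
            else read_property_table(self.properties_path)
        )
        code = get_code(self.genetic_code)
        return NullModel.build(table, build_neighborhood(code))

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {
                "genes": [
                    {"name": g.name, "groups": g.paths} for g in self.genes
                ],
                "properties": self.properties_path,
                "genetic_code": self.genetic_code,
                "z_threshold": self.z_threshold,
                "window": self.window,
                "categories": list(self.categories),
                "groupings": [list(g) for g in self.groupings],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def group_names(self) -> list[str]:
        names: list[str] = []
        for gene in self.genes:
            for group in gene.paths:
                if group not in names:
                    names.append(group)
        return names


@dataclass
class GeneResult:
    gene: str
    n_sites: int
    n_events: int
    n_nonsynonymous: int
    calls: list
    whole_protein: dict


@dataclass
class GroupAnalysis:
    group: str
    results: dict[str, GeneResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def run_group_analysis(config: RunConfig, group: str) -> GroupAnalysis:
    """Run the full chain for every configured gene of one group.

    A stage error aborts that gene with a logged reason and the run
    continues; failures are recorded on the returned analysis.
    """
    null = config.load_null_model()
    code = get_code(config.genetic_code)
    analysis = GroupAnalysis(group=group)
    outdir = config.output / group
    outdir.mkdir(parents=True, exist_ok=True)

    for gene in sorted(config.genes, key=lambda g: g.name):
        if group not in gene.paths:
            continue
        try:
            paths = gene.paths[group]
            alignment = read_codon_alignment(paths["alignment"])
            tree = read_tree(paths["tree"])
            states = fitch_reconstruct(alignment, tree)
            events = enumerate_replacements(states, tree, code)
            observed, n, z = site_zscore_arrays(
                events, null, alignment.n_sites, config.window
            )
            tests = site_profiles(events, null, alignment.n_sites, config.window)
            if config.site_statistic == "band":
                calls = classify_band(
                    events,
                    null,
                    alignment.n_sites,
                    config.window,
                    config.z_threshold,
                    config.categories,
                )
            else:
                calls = classify(tests, config.z_threshold)
            summaries = whole_protein_from_arrays(
                z, null, config.z_threshold, config.categories
            )

            gene_dir = outdir / gene.name
            gene_dir.mkdir(parents=True, exist_ok=True)
            write_events_tsv(events, gene_dir / "events.tsv")
            write_tests_tsv(tests, gene_dir / "ztable.tsv")
            write_calls_tsv(calls, gene_dir / "calls.tsv")
            with open(gene_dir / "whole_protein.tsv", "w") as fh:
                fh.write("property\tsum_z\tthreshold\tpositive\tcategories\n")
                for prop, res in summaries.items():
                    fh.write(
                        f"{prop}\t{res.total:.6g}\t{res.threshold}\t{int(res.positive)}"
                        f"\t{','.join(map(str, config.categories))}\n"
                    )

            n_nonsyn = sum(not e.synonymous for e in events)
            analysis.results[gene.name] = GeneResult(
                gene=gene.name,
                n_sites=alignment.n_sites,
                n_events=len(events),
                n_nonsynonymous=n_nonsyn,
                calls=calls,
                whole_protein=summaries,
            )
            logger.info(
                "group=%s gene=%s sites=%d events=%d nonsyn=%d calls=%d",
                group, gene.name, alignment.n_sites, len(events), n_nonsyn, len(calls),
            )
        except PropselError as exc:
            analysis.failures[gene.name] = str(exc)
            logger.error("group=%s gene=%s failed: %s", group, gene.name, exc)

    _write_manifest(config, analysis, outdir / "manifest.txt")
    return analysis


def _write_manifest(config: RunConfig, analysis: GroupAnalysis, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"propsel_version\t{__version__}\n")
        fh.write(f"config_hash\t{config.config_hash()}\n")
        fh.write(f"group\t{analysis.group}\n")
        fh.write(f"genetic_code\t{config.genetic_code}\n")
        fh.write(f"z_threshold\t{config.z_threshold}\n")
        fh.write(f"window\t{config.window}\n")
        fh.write(f"categories\t{','.join(map(str, config.categories))}\n")
        fh.write("gene\tn_sites\tn_events\tn_nonsynonymous\tn_calls\tstatus\n")
        for name, res in sorted(analysis.results.items()):
            fh.write(
                f"{name}\t{res.n_sites}\t{res.n_events}\t{res.n_nonsynonymous}"
                f"\t{len(res.calls)}\tok\n"
            )
        for name, reason in sorted(analysis.failures.items()):
            fh.write(f"{name}\t-\t-\t-\t-\tfailed: {reason}\n")


def run_comparison(
    config: RunConfig, analyses: dict[str, GroupAnalysis]
) -> GroupComparison:
    """Intersect the groups' positive-destabilizing site sets.

    Requires every gene analyzed in several groups to share its site frame
    (identical number of codon columns); analyses must therefore use one
    master alignment per gene, subset by group.
    """
    if len(analyses) < 2:
        raise ConfigError("need at least 2 completed group analyses")
    frames: dict[str, int] = {}
    for analysis in analyses.values():
        for gene, res in analysis.results.items():
            if gene in frames and frames[gene] != res.n_sites:
                raise FrameError(
                    f"gene {gene}: site frames differ between groups "
                    f"({frames[gene]} vs {res.n_sites} codon sites)"
                )
            frames[gene] = res.n_sites

    null = config.load_null_model()
    call_sets = {}
    for group, analysis in analyses.items():
        per_gene = [
            collect_calls(res.calls, gene, group)
            for gene, res in sorted(analysis.results.items())
        ]
        call_sets[group] = merge_call_sets(per_gene) if per_gene else None
    if any(cs is None for cs in call_sets.values()):
        raise ConfigError("a group analysis produced no gene results")

    comparison = intersect_groups(
        call_sets, config.groupings, properties=null.properties
    )
    logger.info(
        "comparison written; per-property cells are not to be totaled, "
        "deduplicated totals reported separately"
    )
    config.output.mkdir(parents=True, exist_ok=True)
    comparison.to_tsv(config.output / "comparison.tsv")
    return comparison
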