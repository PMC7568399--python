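"""End-to-end design runs: alignment → tree → weights → consensus → filter.

:func:`run_design` wires the individual modules into one reproducible run.
Given an alignment with a designated query (and optionally an outgroup for
rooting and a structure for geometric screening), it emits into the output
directory:

* ``tree.nwk`` — the rooted (or unrooted, if no outgroup) NJ tree;
* ``weights.tsv`` — raw and normalized sequence weights;
* ``profile.tsv`` — the per-position consensus profile;
* ``candidates.tsv`` — the candidate substitutions with filter status;
* ``filter_report.tsv`` — which homologs were removed and why;
* ``manifest.json`` — the full configuration echo plus package/library
  versions, sufficient to replay the run bit-identically.

Any stage failure aborts the run with the stage name attached and removes
partial outputs, so an output directory either holds a complete run or
nothing.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .consensus import candidate_sites, column_frequencies, sites_to_frame
from .errors import ConfigError, StageError
from .family_io import (
    filter_homologs,
    filter_report,
    read_alignment,
    write_filter_report,
)
from .phylogeny import distance_matrix, neighbor_joining, root_with_outgroup
from .structure_filter import (
    MIN_ACTIVE_SITE_DISTANCE,
    apply_structural_filters,
    filter_audit_frame,
    load_structure,
)
from .weighting import branch_weights, uniform_weights


@dataclass
class RunConfig:
    """Everything a design run depends on; echoed into the manifest."""

    alignment: str
    query_id: str | None = None
    outgroup_id: str | None = None
    alignment_format: str = "fasta"
    structure: str | None = None
    structure_chain: str = "A"
    structure_offset: int = 0
    active_site: tuple[int, ...] = ()
    output_dir: str = "design_out"
    min_identity: float = 0.5
    length_tolerance: float = 0.2
    consensus_cutoff_pct: float = 40.0
    cutoff_basis: str = "total"
    min_active_site_distance: float = MIN_ACTIVE_SITE_DISTANCE
    weighting_strategy: str = "equal-split"
    prefilter: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.consensus_cutoff_pct < 100.0):
            raise ConfigError("consensus cutoff must lie in (0, 100)")
        if self.min_active_site_distance <= 0:
            raise ConfigError("min_active_site_distance must be positive")
        if not Path(self.alignment).exists():
            raise ConfigError(f"alignment '{self.alignment}' does not exist")
        if self.structure is not None and not Path(self.structure).exists():
            raise ConfigError(f"structure '{self.structure}' does not exist")
        if self.structure is not None and not self.active_site:
            raise ConfigError("structural filtering needs an active-site list")


@dataclass
class DesignReport:
    """In-memory results of a run (the TSVs hold the same content)."""

    config: RunConfig
    family_size: int
    removed: dict[str, str]
    tree_newick: str
    weights: dict[str, float]
    sites: list
    output_dir: Path
    manifest: dict = field(default_factory=dict)

    @property
    def n_candidates(self) -> int:
        return len(self.sites)

    @property
    def passed_sites(self):
        return [s for s in self.sites if s.filter_status == "passed"]


def _manifest(config: RunConfig) -> dict:
    import Bio
    import dendropy
    import numpy
    import pandas
    import scipy

    return {
        "config": dataclasses.asdict(config),
        "versions": {
            "phyloconsensus": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "biopython": Bio.__version__,
            "dendropy": dendropy.__version__,
        },
    }


def run_design(config: RunConfig) -> DesignReport:
    """Execute the full consensus-design pipeline; see the module docstring."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "read_alignment"
    try:
        family = read_alignment(
            config.alignment, config.alignment_format, config.query_id
        )
        stage = "filter_homologs"
        if config.prefilter:
            removed = filter_report(
                family, config.min_identity, config.length_tolerance
            )
            family = filter_homologs(
                family, config.min_identity, config.length_tolerance
            )
        else:
            removed = {}
        write_filter_report(removed, emit("filter_report.tsv"))

        stage = "distance_matrix"
        dm = distance_matrix(family)
        stage = "neighbor_joining"
        tree = neighbor_joining(dm)
        stage = "rooting"
        if config.outgroup_id is not None:
            tree = root_with_outgroup(tree, config.outgroup_id)
            stage = "weighting"
            weights = branch_weights(
                tree, config.outgroup_id, config.weighting_strategy
            )
        else:
            warnings.warn(
                "no outgroup given: tree left unrooted, uniform weights used",
                stacklevel=2,
            )
            stage = "weighting"
            weights = uniform_weights(family.ids)
        tree.write_newick(emit("tree.nwk"))
        weights.to_tsv(emit("weights.tsv"))

        stage = "consensus"
        profile = column_frequencies(family, weights)
        profile.to_tsv(emit("profile.tsv"))
        sites = candidate_sites(
            profile, family, config.consensus_cutoff_pct, config.cutoff_basis
        )

        stage = "structural_filter"
        if config.structure is not None:
            model = load_structure(
                config.structure,
                family.query_sequence,
                chain=config.structure_chain,
                offset=config.structure_offset,
            )
            sites = apply_structural_filters(
                sites, model, list(config.active_site),
                config.min_active_site_distance,
            )
            filter_audit_frame(sites).to_csv(
                emit("filter_audit.tsv"), sep="\t", index=False
            )
        else:
            warnings.warn(
                "no structure given: structural filtering skipped",
                stacklevel=2,
            )

        stage = "report"
        sites_to_frame(sites).to_csv(
            emit("candidates.tsv"), sep="\t", index=False
        )
        manifest = _manifest(config)
        with open(emit("manifest.json"), "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    return DesignReport(
        config=config,
        family_size=len(family),
        removed=removed,
        tree_newick=tree.as_newick(),
        weights=dict(weights.weights),
        sites=sites,
        output_dir=out,
        manifest=manifest,
    )
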