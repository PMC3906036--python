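"""End-to-end pipeline grid: chip descriptions x normalization engines.

Builds the three chip descriptions (vendor/standard, merged re-annotated,
3'-restricted re-annotated) from a probe table and transcriptome, runs
every requested normalization engine on the matched frozen/FFPE matrices,
and collects one :class:`~ffpearray.concordance.ConcordanceReport` per
pipeline.  This is the machinery behind the ``benchmark`` CLI subcommand
and the reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import cdf as cdfmod
from .concordance import BenchmarkConfig, ConcordanceReport, concordance_report
from .errors import ConfigurationError
from .normalization import FrozenParameters, estimate_frozen_parameters, normalize

DEFAULT_METHODS = ("mas5", "rma", "frma")
DEFAULT_VARIANTS = ("standard", "refseq_all", "refseq_dist")


@dataclass(frozen=True)
class PipelineSpec:
    """One (normalization method, chip description) combination."""

    method: str
    description: str
    frozen_path: str | None = None

    def __post_init__(self):
        if self.method == "frma" and self.frozen_path is None:
            # at grid-run time frozen parameters may be estimated in memory;
            # a path is only mandatory when specs come from configuration files
            pass

    @property
    def name(self) -> str:
        return f"({self.method}, {self.description})"


def build_descriptions(
    probes: Sequence[cdfmod.Probe],
    transcripts: Mapping[str, cdfmod.Transcript],
    min_probes: int = 5,
    n_dist_probes: int = 5,
    distance_cutoff: int = 300,
    min_dist_probes: int = 5,
    revcomp_probes: bool = False,
) -> dict[str, cdfmod.ChipDescription]:
    """Standard, merged (refseq_all) and 3'-restricted (refseq_dist)
    descriptions from one probe table and transcriptome."""
    hits = cdfmod.map_probes(probes, transcripts, revcomp_probes=revcomp_probes)
    return {
        "standard": cdfmod.build_standard_description(probes),
        "refseq_all": cdfmod.build_refseq_all(hits, min_probes=min_probes),
        "refseq_dist": cdfmod.build_refseq_dist(
            hits,
            n_dist_probes=n_dist_probes,
            distance_cutoff=distance_cutoff,
            min_dist_probes=min_dist_probes,
        ),
    }


def run_benchmark(
    frozen: pd.DataFrame,
    ffpe: pd.DataFrame,
    annotation: pd.DataFrame,
    descriptions: Mapping[str, cdfmod.ChipDescription],
    reference_batches: Sequence[pd.DataFrame] | None = None,
    frozen_parameters: Mapping[str, FrozenParameters] | None = None,
    methods: Sequence[str] = DEFAULT_METHODS,
    config: BenchmarkConfig = BenchmarkConfig(),
    leave_one_out_for: Sequence[str] = (),
) -> list[ConcordanceReport]:
    """Run every (method, description) pipeline and rate its concordance.

    ``frma`` needs frozen parameters: pass them per description name, or
    pass ``reference_batches`` and they are estimated here.
    ``leave_one_out_for`` names pipelines (e.g. ``"(frma, refseq_all)"``)
    for which the leave-one-out robustness analysis is added.
    """
    frozen_parameters = dict(frozen_parameters or {})
    if "frma" in methods:
        for name, cd in descriptions.items():
            if name not in frozen_parameters:
                if reference_batches is None:
                    raise ConfigurationError(
                        "frma requested without frozen parameters or reference batches"
                    )
                frozen_parameters[name] = estimate_frozen_parameters(
                    reference_batches, cd
                )
    reports = []
    for desc_name, cd in descriptions.items():
        for method in methods:
            expr_f = normalize(
                frozen, cd, method, frozen=frozen_parameters.get(desc_name)
            )
            expr_p = normalize(
                ffpe, cd, method, frozen=frozen_parameters.get(desc_name)
            )
            pipeline = f"({method}, {desc_name})"
            reports.append(
                concordance_report(
                    pipeline,
                    expr_f,
                    expr_p,
                    annotation,
                    config=config,
                    leave_one_out=pipeline in leave_one_out_for,
                )
            )
    return reports


def reports_table(reports: Sequence[ConcordanceReport]) -> pd.DataFrame:
    """Flat metric table (one row per pipeline), in report order."""
    return pd.DataFrame([r.summary() for r in reports]).set_index("pipeline")
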