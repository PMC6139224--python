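"""End-to-end orchestration of the integrative analysis on one cohort.

Chains the layers in the study's order: differential expression with
covariate adjustment, probe annotation, differential methylation with
filtering, and the expression-methylation integration that yields the
methylation-regulated DEG (MeDEG) table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import annotate_probes
from .expression import DifferentialExpressionModel, DifferentialExpressionResults
from .integration import IntegrationModel, MeDegResults
from .methylation import DifferentialMethylationModel, DifferentialMethylationResults
from .simulate import Cohort

__all__ = ["PipelineResults", "run_pipeline"]


@dataclass
class PipelineResults:
    expression: DifferentialExpressionResults
    methylation: DifferentialMethylationResults
    contexts: pd.DataFrame
    integration: MeDegResults

    def summary(self) -> str:
        return "\n\n".join(
            [
                self.expression.summary(),
                self.methylation.summary(),
                self.integration.summary(),
            ]
        )


def run_pipeline(
    cohort: Cohort,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.5,
    db_thresh: float = 0.12,
    p_detect: float = 0.01,
    covariates: str | pd.DataFrame | None = "auto",
    meth_mode: str = "ranksum",
) -> PipelineResults:
    """Run the full integrative analysis on a cohort."""
    expr_res = DifferentialExpressionModel(
        cohort.expression,
        cohort.metadata,
        covariates=covariates,
        annotation=cohort.expr_annotation,
    ).fit(p_thresh=p_thresh, fc_thresh=fc_thresh)

    contexts = annotate_probes(
        cohort.meth_annotation, cohort.gene_models, cohort.cpg_islands
    )
    meth_res = DifferentialMethylationModel(
        cohort.methylation,
        cohort.detection,
        cohort.meth_annotation,
        cohort.metadata,
        probe_gene=contexts["gene_id"],
    ).fit(p_detect=p_detect, p_thresh=p_thresh, db_thresh=db_thresh, mode=meth_mode)

    integration = IntegrationModel(
        expr_res,
        meth_res,
        cohort.expression,
        cohort.methylation,
        cohort.expr_annotation,
        contexts,
    ).fit()
    return PipelineResults(expr_res, meth_res, contexts, integration)
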