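"""One-call orchestration: generate (or load) sources, build, classify."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .classification import FIVE_YEAR_WINDOW_DAYS, classify_index
from .index import MasterIndex, build_master_index
from .linkage import LinkageConfig
from .prevalence import (EvaluationResult, PairwiseLinkageResult,
                         evaluate_against_truth, pairwise_linkage_metrics)
from .synthetic import GeneratorConfig, SyntheticDataset


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    index: MasterIndex

    def linkage_metrics(self) -> PairwiseLinkageResult:
        return pairwise_linkage_metrics(self.index.record_to_uid(),
                                        self.dataset.record_truth_map())

    def evaluation(self) -> EvaluationResult:
        return evaluate_against_truth(self.index, self.dataset.truth,
                                      self.dataset.record_truth_map())


def run_pipeline(gen_config: GeneratorConfig,
                 link_config: Optional[LinkageConfig] = None,
                 window_days: int = FIVE_YEAR_WINDOW_DAYS,
                 dataset: Optional[SyntheticDataset] = None) -> PipelineResult:
    """Generate a synthetic dataset (unless given one), index and classify it."""
    if dataset is None:
        dataset = SyntheticDataset.generate(gen_config)
    index = build_master_index(dataset.records,
                               link_config or LinkageConfig(),
                               period=gen_config.period)
    classify_index(index, window_days)
    return PipelineResult(dataset=dataset, index=index)
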