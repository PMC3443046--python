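import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from longamp import PipelineConfig, SimConfig, make_panel, run_validation_experiment, simulate_reads
from longamp.align import align_all
from longamp.simulate import truth_to_alignment


@pytest.fixture(scope="session")
def study_sim():
    """Seeded simulation at the study error rates: panel, sample, truth, reads, truths."""
    cfg = SimConfig(seed=42, depth=35)
    panel, sample, truth = make_panel(cfg, n_amplicons=2)
    reads, truths = simulate_reads(panel, sample, cfg)
    return cfg, panel, sample, truth, reads, truths


@pytest.fixture(scope="session")
def study_alignments(study_sim):
    """Aligner output plus truth-walk alignments for the same reads."""
    cfg, panel, sample, truth, reads, truths = study_sim
    alignments, unaligned = align_all(reads, panel)
    true_alns = [truth_to_alignment(t, r) for t, r in zip(truths, reads)]
    refs = {a.name: a.bases for a in panel.amplicons}
    return alignments, unaligned, true_alns, refs


@pytest.fixture(scope="session")
def validation_run():
    """Full end-to-end validation experiment: 98 sites, 70x, study error rates."""
    cfg = PipelineConfig(sim=SimConfig(seed=7, depth=70))
    return run_validation_experiment(cfg)
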