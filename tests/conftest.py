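import numpy as np
import pytest

from ecochg import analysis as ana
from ecochg import synthesis as syn


@pytest.fixture
def noiseless_cfg():
    return syn.GeneratorConfig(noise_sd_uv=0.0, trials_per_polarity=1)


@pytest.fixture
def normal_phenotype():
    return syn.SubjectPhenotype.normal()


@pytest.fixture
def click_pair(noiseless_cfg, normal_phenotype):
    """Noiseless condensation/rarefaction single-click epochs at 120 dB."""
    def make(level=120.0, phenotype=None, cfg=None):
        ph = phenotype or normal_phenotype
        c = cfg or noiseless_cfg
        cond = syn.synthesize_trial(
            ph, syn.StimulusSpec(level, "condensation"), c)
        rar = syn.synthesize_trial(
            ph, syn.StimulusSpec(level, "rarefaction"), c)
        return cond, rar
    return make


@pytest.fixture
def measured_metrics(click_pair):
    """Full noiseless chain at one level -> (metrics, components)."""
    def run(level=120.0, phenotype=None):
        cond, rar = click_pair(level, phenotype)
        mean = ana.cancel_cm(cond, rar)
        cm = ana.extract_cm(cond, mean)
        onset = ana.detect_cm_onset(cm)
        return ana.measure_potentials(mean, onset), onset
    return run


def components_sum(phenotype, level, cfg):
    comp = syn.component_waveforms(
        phenotype, syn.StimulusSpec(level, "condensation"), cfg)
    return comp
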