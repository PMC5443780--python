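"""Shared fixtures: one standard synthetic community and its full
two-round pipeline result, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from metasecretome.matcher import MatchConfig
from metasecretome.pipeline import RunMeta, run_two_round
from metasecretome.quant import quantify
from metasecretome.simulate import CommunitySpec, generate_assembly, generate_spectra


@pytest.fixture(scope="session")
def community():
    """Default 30-protein community, seed 1."""
    return generate_assembly(CommunitySpec.default(seed=1))


@pytest.fixture(scope="session")
def runs_with_truth(community):
    """All six (fraction x replicate) runs with ground-truth PSM tables."""
    out = []
    for fraction in community.spec.fractions:
        for rep in range(1, community.spec.n_replicates + 1):
            spectra, truth = generate_spectra(community, fraction, rep)
            out.append((RunMeta("SYN", fraction, rep), spectra, truth))
    return out


@pytest.fixture(scope="session")
def pipeline_result(community, runs_with_truth):
    """(round1, library, identifications) of the full two-round search."""
    runs = [(meta, spectra) for meta, spectra, _truth in runs_with_truth]
    return run_two_round(runs, community.contigs, MatchConfig())


@pytest.fixture(scope="session")
def quant_table(pipeline_result):
    _r1, library, idents = pipeline_result
    return quantify(idents, library.as_dict())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
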