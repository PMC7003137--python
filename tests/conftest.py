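"""Shared fixtures: a desk-scale calibrated population and synthetic drug
panel, reused session-wide so the ODE work is paid once.

The fast suite paces with 50 pre-pacing beats (a documented deviation from
the 150-beat protocol used for reported results) to keep the full run in
minutes on one CPU.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from torsim.ord_model import PacingProtocol
from torsim import pharm, synth

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: pre-pacing depth for the fast suite (reported runs use 150)
FAST_BEATS = 50


@pytest.fixture(scope="session")
def fast_protocol() -> PacingProtocol:
    return PacingProtocol(n_beats=FAST_BEATS)


@pytest.fixture(scope="session")
def fixture_population(fast_protocol):
    """Six calibrated RA-prone members (deterministic seed)."""
    return synth.generate_fixture_population(size=6, seed=3,
                                             protocol=fast_protocol)


@pytest.fixture(scope="session")
def drug_panel():
    """Synthetic panel with two compounds per archetype (hERG margins
    0.03 and 0.1) and its archetype labels."""
    return synth.generate_drug_panel(n_per_archetype=2, seed=1)


@pytest.fixture(scope="session")
def panel_trials(fixture_population, drug_panel, fast_protocol):
    """ALL7 trial results for the ground-truth compounds (both pure-hERG,
    both inactive, both balanced)."""
    drugs, labels = drug_panel
    wanted = {name for name, a in labels.items()
              if a in ("pure_herg", "inactive", "balanced_multichannel")}
    results = {}
    for d in drugs:
        if d.compound_name in wanted:
            results[d.compound_name] = pharm.run_trial(
                d, fixture_population, protocol=fast_protocol)
    return results, labels
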