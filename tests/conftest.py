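import hypothesis
import hypothesis.strategies as st
import pytest

import adductscreen as asc

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("ci")


#: Strategy for random CHNOPS compositions. Total atom count ≥ 4 so every
#: derived ion (including the deprotonated molecule) has a defined 3N−6 DOF.
compositions = st.builds(
    asc.ElementCounts,
    st.fixed_dictionaries(
        {"C": st.integers(1, 40), "H": st.integers(1, 60)},
        optional={
            "N": st.integers(1, 10),
            "O": st.integers(1, 20),
            "P": st.integers(1, 4),
            "S": st.integers(1, 4),
        },
    ),
).filter(lambda c: c.atom_count >= 4)


@pytest.fixture(scope="session")
def panel():
    return asc.paper_like_panel()


@pytest.fixture(scope="session")
def noise_free_sim(panel):
    """Noise-free simulated run set with its ground truth (shared, read-only)."""
    cfg = asc.SimConfig(seed=7, noise_cv=0.0)
    runs, gt = asc.simulate_run_set(panel, cfg)
    return runs, gt, cfg


@pytest.fixture(scope="session")
def default_settings(noise_free_sim):
    _, gt, _ = noise_free_sim
    return asc.CollisionSettings(reference_dof=gt["reference_dof"])
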