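import pytest

from ductokym.simdata import preset, simulate_movie


@pytest.fixture(scope="session")
def fig1():
    """The fig1 preset movie and its ground truth (240 s, 1 fps, seed 42)."""
    return simulate_movie(preset("fig1"))


@pytest.fixture(scope="session")
def fig1_stack(fig1):
    return fig1[0]


@pytest.fixture(scope="session")
def fig1_truth(fig1):
    return fig1[1]


@pytest.fixture(scope="session")
def peristaltic():
    """Peristaltic preset: wave speed 50 px/s, 7 frames/s."""
    return simulate_movie(preset("peristaltic"))


@pytest.fixture(scope="session")
def net_flow_movie():
    return simulate_movie(preset("net_flow"))


@pytest.fixture(scope="session")
def pendular_flow_movie():
    return simulate_movie(preset("pendular_flow"))


@pytest.fixture(scope="session")
def drug_response_events():
    """Detected events on the drug_response preset, single mid-duct line."""
    from ductokym.contract import detect_contractions, trace_diameter
    from ductokym.kymo import extract_kymograph
    from _util import vline

    stack, truth = simulate_movie(preset("drug_response"))
    line = vline(96.0, 10.0, 86.0, line_id="mid")
    trace = trace_diameter(extract_kymograph(stack, line))
    return detect_contractions(trace), truth
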