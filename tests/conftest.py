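import numpy as np
import pytest

from polaroi import engine, roimaker, synth


@pytest.fixture(scope="session")
def deiters_movie():
    """Default polarized-cell movie with transients, plus its ground truth."""
    return synth.render_movie(synth.default_deiters_spec(seed=1))


@pytest.fixture(scope="session")
def deiters_layout(deiters_movie):
    stack, _ = deiters_movie
    return roimaker.build_layout(stack.frames[0])


@pytest.fixture(scope="session")
def quiet_cell_frame():
    """Single noise-free-transient frame (no stimulus, no drift) + truth."""
    spec = synth.default_deiters_spec(
        seed=5,
        n_frames=1,
        soma_transient=synth.TransientSpec(peak_dff=0.0),
        process_transient=synth.TransientSpec(peak_dff=0.0),
    )
    return synth.render_movie(spec)


@pytest.fixture(scope="session")
def drift_movie():
    """Thin near-horizontal cell with a 15 px perpendicular step at frame 20."""
    spec = synth.default_deiters_spec(
        seed=3,
        shape=(200, 200),
        soma_semi_axes=(50.0, 10.0),
        process_length=30.0,
        theta_deg=0.0,
        n_frames=40,
        soma_transient=synth.TransientSpec(peak_dff=0.0),
        process_transient=synth.TransientSpec(peak_dff=0.0),
        drift=((20, 15, 0),),
    )
    return synth.render_movie(spec)


@pytest.fixture(scope="session")
def deiters_run(deiters_movie):
    stack, _ = deiters_movie
    return engine.run(stack, engine.RunConfig())


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
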