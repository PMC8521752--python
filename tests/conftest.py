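import pytest

import cannoxclass as cx


@pytest.fixture(scope="session")
def cfg():
    return cx.default_scheme_config()


@pytest.fixture(scope="session")
def panel_bundle(cfg):
    """Default labelled panel at seed 1, background rate 0, masked."""
    panel, labels, real = cx.default_panel(cfg, seed=1)
    return panel, labels, real


@pytest.fixture(scope="session")
def scheme(cfg, panel_bundle):
    panel, labels, _real = panel_bundle
    return cx.build_scheme(panel, labels, cfg)


@pytest.fixture(scope="session")
def scheme_factory(cfg, scheme):
    """Schemes are realization-specific (placeholder states depend on the
    generated ancestor), so round-trip checks pair each panel with the
    scheme built from the same seed."""
    cache = {1: scheme}

    def get(seed: int):
        if seed not in cache:
            panel, labels, _real = cx.default_panel(cfg, seed)
            cache[seed] = cx.build_scheme(panel, labels, cfg)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def panel_frames(panel_bundle):
    panel, _labels, real = panel_bundle
    ref = real.prototypes["1/1"].seq
    return {
        s.id: (s, cx.build_frame(cx.align_global(ref, s))) for s in panel
    }
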