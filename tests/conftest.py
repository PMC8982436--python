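import numpy as np
import pytest

from embryoquant import SimConfig
from embryoquant.synth import (
    assign_domains,
    build_cell_lattice,
    nuclei_mask,
    render_channels,
    simulate_transcription,
)


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimConfig:
    """Low-density, noise-free imaging regime with enforced spot separation."""
    return SimConfig(
        n_cols=6, n_rows=4, cell_pitch_px=48, jitter=0.2, psf_sigma_px=1.3,
        k_tx=3.0, noise_sd=0.0, min_spot_sep_px=6.0, leak_frac=0.0,
        domains={"rho": (0.2, 0.8), "mir9a": (0.1, 0.8)}, seed=17,
    )


@pytest.fixture(scope="session")
def noiseless_embryo(noiseless_cfg):
    cm = build_cell_lattice(noiseless_cfg)
    flags = assign_domains(cm, noiseless_cfg)
    gt = simulate_transcription(cm, flags, noiseless_cfg, "WT")
    stack, spots = render_channels(cm, gt, noiseless_cfg)
    return {
        "cfg": noiseless_cfg, "cellmap": cm, "flags": flags, "gt": gt,
        "stack": stack, "spots": spots,
        "nuclei_mask": nuclei_mask(cm, noiseless_cfg),
    }


@pytest.fixture(scope="session")
def default_embryo():
    """One embryo at the default (realistic-SNR) study conditions."""
    cfg = SimConfig(seed=5)
    cm = build_cell_lattice(cfg)
    flags = assign_domains(cm, cfg)
    gt = simulate_transcription(cm, flags, cfg, "WT")
    stack, spots = render_channels(cm, gt, cfg)
    return {
        "cfg": cfg, "cellmap": cm, "flags": flags, "gt": gt,
        "stack": stack, "spots": spots, "nuclei_mask": nuclei_mask(cm, cfg),
    }


@pytest.fixture
def square_grid_labels():
    """3x3 lattice of 10x10-px square cells, labels 1..9 row-major."""
    lab = np.zeros((30, 30), dtype=np.int32)
    for r in range(3):
        for c in range(3):
            lab[r * 10:(r + 1) * 10, c * 10:(c + 1) * 10] = 3 * r + c + 1
    return lab
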