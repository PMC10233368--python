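
import pandas as pd
import pytest

from dotscreen import calling, quantify
from dotscreen.simulate import ScreenConfig, generate_screen


def analyze_screen(screen, min_replicates=3, z_threshold=10.0,
                   preference_threshold=2.0):
    """Quantify every membrane of a synthetic screen and call preferences.

    Returns (dots, sets, pairs, floors); the shared happy path used by
    many tests.
    """
    cfg = screen.config
    dots = {}
    for mem_id, img in screen.images.items():
        grid = quantify.fit_grid(img, rows=cfg.grid_rows, cols=cfg.grid_cols)
        dots[mem_id] = quantify.quantify_dots(img, grid, membrane_id=mem_id)
    all_dots = pd.concat(dots.values(), ignore_index=True)
    sets = calling.build_normalized_sets(
        all_dots, screen.plate_map, min_replicates=min_replicates
    )
    sets = calling.apply_exclusions(
        sets, screen.od_table, z_threshold=z_threshold
    )
    floors = calling.detection_floors(dots, screen.plate_map)
    pairs = calling.call_pairs(
        sets, cfg.baits,
        preference_threshold=preference_threshold,
        detection_floor=max(floors.values()),
    )
    return dots, sets, pairs, floors


@pytest.fixture(scope="session")
def tiny_config():
    """24 preys on an 8x12 grid, block layout (quarter of positions empty)."""
    return ScreenConfig(
        n_preys=24, grid_rows=8, grid_cols=12, seed=3,
        missing_strain_fraction=0.0,
    )


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    return generate_screen(tiny_config)


@pytest.fixture(scope="session")
def noise_free_screen():
    """Noise-free membranes: the quantification oracle conditions."""
    cfg = ScreenConfig(
        n_preys=24, grid_rows=8, grid_cols=12, seed=3,
        read_noise_sd=0.0, replicate_cv=0.0, background_gradient=0.0,
        missing_strain_fraction=0.0,
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def full_screen():
    """The screen at study conditions: 512 preys in a 1,536-dot array,
    planted fractions (null .5, equal .3, prefers_A .1, prefers_B .1),
    true fold change 4, replicate CV 0.1, 3 bio x 3 tech replicates."""
    return generate_screen(ScreenConfig(seed=20240917))


@pytest.fixture(scope="session")
def full_screen_analysis(full_screen):
    dots, sets, pairs, floors = analyze_screen(full_screen)
    merged = pairs.merge(
        full_screen.truth.preys, on="prey_id", suffixes=("_called", "_true")
    )
    return {
        "screen": full_screen,
        "dots": dots,
        "sets": sets,
        "pairs": pairs,
        "floors": floors,
        "merged": merged,
    }


@pytest.fixture()
def small_pipeline_config(tmp_path):
    from dotscreen.pipeline import PipelineConfig

    screen = ScreenConfig(
        n_preys=24, grid_rows=8, grid_cols=12, n_bio_reps=2,
        missing_strain_fraction=0.0, seed=5,
    )
    return PipelineConfig(screen=screen, seed=5)
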