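import numpy as np
import pytest
from hypothesis import settings

from gliaclone.model import Cell, Clone
from gliaclone.synth import SynthConfig, generate_startrack_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_clone(type_counts, sample_id="s1", clone_key="100000000000", **cell_kwargs):
    """Small clone factory: {"BG": 3, "GLA": 5} -> a 8-cell clone."""
    cells = []
    i = 0
    for cell_type, n in type_counts.items():
        for _ in range(n):
            cells.append(
                Cell(
                    cell_id=f"c{i}",
                    clone_key=clone_key,
                    cell_type=cell_type,
                    lobule=cell_kwargs.get("lobule", "IV-V"),
                    wall=cell_kwargs.get("wall", "wall_A"),
                    section_index=cell_kwargs.get("section_index", 1),
                    coords=cell_kwargs.get("coords"),
                )
            )
            i += 1
    return Clone(cells=cells, sample_id=sample_id)


@pytest.fixture(scope="session")
def startrack_dataset():
    """One deterministic synthetic StarTrack-like sample with ground truth."""
    return generate_startrack_dataset(SynthConfig(seed=42, n_clones=120))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
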