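import pytest

from canopyspec import imaging, models, preprocess, synth
from canopyspec.grids import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def banded_scene(grid):
    """A 96x96 three-severity scene rendered with default statistics."""
    spec = synth.make_scene(96, 96, layout="bands", seed=5)
    raw, white, dark, mask, labels = synth.render_scene(spec, grid)
    return dict(spec=spec, raw=raw, white=white, dark=dark,
                truth_mask=mask, truth_labels=labels)


@pytest.fixture(scope="session")
def calibrated_scene(grid, banded_scene):
    cube = imaging.calibrate_cube(
        imaging.RawCube(banded_scene["raw"], grid),
        imaging.ReferenceFrame(banded_scene["white"], "white"),
        imaging.ReferenceFrame(banded_scene["dark"], "dark"))
    return cube


@pytest.fixture(scope="session")
def split_table(grid):
    """A 3x150 labeled spectra table with assigned cal/val/test splits."""
    table = synth.sample_spectra_table(
        {c: 150 for c in ("control", "early", "severe")}, seed=42, grid=grid)
    return models.stratified_split(table, models.SplitSpec(seed=42))


@pytest.fixture(scope="session")
def snv_splits(split_table):
    """(Xc, yc, Xv, yv, Xt, yt) after SNV preprocessing fitted on cal."""
    pre = preprocess.Preprocessor(["snv"])
    cal = split_table.rows("cal")
    val = split_table.rows("val")
    test = split_table.rows("test")
    Xc = pre.fit_transform(cal.X)
    return (Xc, cal.labels, pre.transform(val.X), val.labels,
            pre.transform(test.X), test.labels, pre)
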