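import numpy as np
import pandas as pd
import pytest

from mifspatial.io_cells import PANEL_MARKERS, TissueSite


def site_from_points(points, panel="combined", region="IM", patient_id="P1",
                     core_index=1, extent=None, compartment="stroma"):
    """Build a phenotyped site from {label: [(x, y), ...]} with blank markers."""
    rows = []
    i = 0
    for label, coords in points.items():
        for x, y in coords:
            rows.append({"cell_id": f"c{i}", "x": float(x), "y": float(y),
                         "compartment": compartment, "phenotype": label})
            i += 1
    df = pd.DataFrame(rows, columns=["cell_id", "x", "y", "compartment", "phenotype"])
    for m in PANEL_MARKERS[panel]:
        df[m] = False
    return TissueSite(patient_id=patient_id, region=region, core_index=core_index,
                      panel_id=panel, df=df, extent=extent)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_site(rng, n_by_label, radius=500.0, **kwargs):
    """Uniform random points on a disc per phenotype label."""
    points = {}
    for label, n in n_by_label.items():
        r = radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        points[label] = list(zip(r * np.cos(th), r * np.sin(th)))
    return site_from_points(points, **kwargs)
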