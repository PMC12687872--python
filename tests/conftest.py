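import numpy as np
import pandas as pd
import pytest

from aisgeom.records import CellRecord
from aisgeom.builder import (BiophysSpec, ChannelDensities, SECTION_CLASSES,
                             Section, CompartmentGraph)


@pytest.fixture(scope="session")
def ca1_record() -> CellRecord:
    """A typical non-AcD CA1 pyramidal cell geometry."""
    return CellRecord(
        cell_id="ca1-ref", plane="ventral", subregion="CA1m",
        soma_major=17.0, soma_minor=11.0,
        apical_diams=(2.6, 2.4, 2.2, 2.0, 1.8),
        ais_distance=5.5, ais_length=25.0,
        ais_d_start=1.15, ais_d_max=1.25, ais_d_end=0.55, ais_max_pos=2.5,
        acd_stem_length=0.0,
    )


@pytest.fixture(scope="session")
def acd_record() -> CellRecord:
    """An AcD cell with a 6 µm stem."""
    return CellRecord(
        cell_id="acd-ref", plane="ventral", subregion="CA1m",
        soma_major=17.0, soma_minor=11.0,
        apical_diams=(2.6, 2.4, 2.2, 2.0, 1.8),
        ais_distance=8.0, ais_length=25.0,
        ais_d_start=1.15, ais_d_max=1.25, ais_d_end=0.55, ais_max_pos=2.5,
        acd_stem_length=6.0, acd_stem_diam=1.3,
    )


def passive_biophys(g_pas: float = 1e-4, ra: float = 150.0, cm: float = 1.0,
                    e_pas: float = -70.0) -> BiophysSpec:
    dens = {cls: ChannelDensities(g_pas=g_pas, gna=0.0, gk=0.0)
            for cls in SECTION_CLASSES}
    return BiophysSpec(ra=ra, cm=cm, v_init=e_pas, ena=55.0, ek=-90.0,
                       e_pas=e_pas, densities=dens)


@pytest.fixture(scope="session")
def passive_cylinder():
    """Single uniform passive cable, sealed ends, finely discretized."""
    bio = passive_biophys()
    sec = {"soma": Section("soma", "soma", 1000.0, [(0.0, 2.0), (1.0, 2.0)],
                           None, nseg=101)}
    return CompartmentGraph(sections=sec, biophys=bio)


@pytest.fixture(scope="session")
def small_cohort():
    from aisgeom.cohort import default_profiles, generate_frame

    prof = default_profiles()["ventral-CA1m"]
    return generate_frame(prof, 400, seed=7)
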