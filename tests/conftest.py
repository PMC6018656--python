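import io

import pandas as pd
import pytest

from consensusclick.io import RAW_COLUMNS
from consensusclick.simulate import VolunteerProfile, generate_scene, simulate_clicks

RAW_DEFAULTS = {
    "user_name": "vol_a",
    "subject_zooniverse_id": "S1",
    "lunar_phase": "full",
    "original_size_x": "1920",
    "original_size_y": "1080",
    "path": "DAMOa/DAMOa2014a_000025",
    "temperature_f": "32",
    "timestamp": "2014:01:01 12:00:00",
    "animals_present": "yes",
    "all_marked": "complete",
    "value": "adult",
    "x": "100.0",
    "y": "100.0",
}


def raw_csv(rows: list[dict]) -> io.StringIO:
    """Raw-classification CSV text from partial row dicts (defaults filled)."""
    full = [{**RAW_DEFAULTS, **row} for row in rows]
    df = pd.DataFrame(full, columns=list(RAW_COLUMNS))
    return io.StringIO(df.to_csv(index=False))


@pytest.fixture
def ideal_volunteers():
    """Ten perfect volunteers: every target found, tight clicks, true labels."""
    return [VolunteerProfile.ideal(click_noise_px=2.0)] * 10


@pytest.fixture
def small_scene():
    """Well-separated colony: 5 adults + 2 chicks, 50 px apart."""
    return generate_scene(n_adults=5, n_chicks=2, min_separation=50.0, seed=11)


@pytest.fixture
def ideal_raw_table(small_scene, ideal_volunteers):
    return simulate_clicks(
        small_scene,
        ideal_volunteers,
        seed=12,
        subject_id="SYNTHa2014a_000001",
        path="SYNTHa/SYNTHa2014a_000001",
    )
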