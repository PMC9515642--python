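import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import songrhythm as sr

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


@pytest.fixture
def simple_table() -> sr.EventTable:
    """Two phrases of one bout: 4 + 3 notes with hand-set timing."""
    rows = [
        # phrase 0: onsets 0.0, 0.3, 0.5, 0.9 (IOIs 0.3, 0.2, 0.4)
        (0.0, 0.1, "A", 0),
        (0.3, 0.4, "B", 0),
        (0.5, 0.6, "A", 0),
        (0.9, 1.0, "C", 0),
        # phrase 1: onsets 5.0, 5.2, 5.4 (IOIs 0.2, 0.2)
        (5.0, 5.1, "B", 1),
        (5.2, 5.3, "A", 1),
        (5.4, 5.5, "B", 1),
    ]
    df = pd.DataFrame(rows, columns=["onset", "offset", "label", "phrase_id"])
    df["bout_id"] = "b0"
    df["bird_id"] = "bird1"
    return sr.EventTable(df)


@pytest.fixture(scope="session")
def coupled_table() -> sr.EventTable:
    table, _ = sr.generate_song(sr.preset("coupled", n_phrases=300, seed=11))
    return table


@pytest.fixture(scope="session")
def coupled_records(coupled_table) -> pd.DataFrame:
    return sr.rhythm_ratios(sr.compute_iois(coupled_table, level="note"))


@pytest.fixture(scope="session")
def decoupled_table() -> sr.EventTable:
    table, _ = sr.generate_song(sr.preset("decoupled", n_phrases=300, seed=11))
    return table


def make_table(onsets, offsets, labels, phrase_ids, bout="b0", bird="bird1"):
    df = pd.DataFrame(
        {
            "onset": onsets,
            "offset": offsets,
            "label": labels,
            "phrase_id": phrase_ids,
            "bout_id": bout,
            "bird_id": bird,
        }
    )
    return sr.EventTable(df)
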