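import pytest

from odobenus.io import MorphoDataset, MorphoSpecimen, RegionAlignment


def make_specimen(sid, region="MAR", sex="unknown", age=None, **measures):
    """Build a specimen from kwargs like CBL=350, TLC_L=600, TLC_R=610."""
    parsed = {}
    for key, value in measures.items():
        if key.endswith(("_L", "_R")):
            parsed[(key[:-2], key[-1])] = value
        else:
            parsed[(key, None)] = value
    return MorphoSpecimen(
        specimen_id=sid, region=region, sex=sex, age_years=age, measures=parsed
    )


@pytest.fixture
def toy_pairs():
    """Two regions with hand-computable bilateral tusk measurements."""
    return MorphoDataset(
        [
            make_specimen("m1", "MAR", TLC_L=95.0, TLC_R=105.0),
            make_specimen("m2", "MAR", TLC_L=105.0, TLC_R=95.0),
            make_specimen("a1", "ATL", TLC_L=100.0, TLC_R=100.0),
            make_specimen("a2", "ATL", TLC_L=200.0, TLC_R=210.0),
        ]
    )


def make_alignment(rows):
    """rows: list of (sample_id, region, sequence)."""
    return RegionAlignment(records=list(rows), length=len(rows[0][2]))
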