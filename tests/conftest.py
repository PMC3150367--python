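import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from efg_paralogs import profiles
from efg_paralogs.motifs import parse_pattern
from efg_paralogs.synth import make_profile_alignment, subfamily_profile_specs


@pytest.fixture(scope="session")
def subfamily_alignments():
    """The two profile-embedded subfamily alignments (114 + 140 sequences,
    full reference length), generated once per session."""
    spec1, spec2 = subfamily_profile_specs()
    return (
        make_profile_alignment(spec1, seed=11, id_prefix="efg1_"),
        make_profile_alignment(spec2, seed=12, id_prefix="efg2_"),
    )


@pytest.fixture(scope="session")
def g2_patterns():
    return [
        parse_pattern(text, name=name)
        for name, text in profiles.G2_SUB_SUBGROUP_PATTERNS.items()
    ]
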