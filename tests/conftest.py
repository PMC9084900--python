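import pytest
from hypothesis import settings

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def diamond_dag():
    """root <- A1, A2; B is_a both A1 and A2."""
    from symbioscan.enrichment import GoDag

    return GoDag(
        terms={
            "GO:0000001": ("root", "biological_process"),
            "GO:0000002": ("A1", "biological_process"),
            "GO:0000003": ("A2", "biological_process"),
            "GO:0000004": ("B", "biological_process"),
        },
        parents={
            "GO:0000001": set(),
            "GO:0000002": {"GO:0000001"},
            "GO:0000003": {"GO:0000001"},
            "GO:0000004": {"GO:0000002", "GO:0000003"},
        },
    )


@pytest.fixture
def chain_dag():
    """root <- A <- B."""
    from symbioscan.enrichment import GoDag

    return GoDag(
        terms={
            "GO:0000001": ("root", "biological_process"),
            "GO:0000002": ("A", "biological_process"),
            "GO:0000003": ("B", "biological_process"),
        },
        parents={
            "GO:0000001": set(),
            "GO:0000002": {"GO:0000001"},
            "GO:0000003": {"GO:0000002"},
        },
    )
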