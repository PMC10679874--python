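import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from spliceopanel.homology import ScoringScheme
from spliceopanel.panel import Panel, PanelEntry


@pytest.fixture(scope="session")
def blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


@pytest.fixture(scope="session")
def protein_scheme():
    return ScoringScheme.protein_default()


@pytest.fixture
def small_panel():
    return Panel(
        [
            PanelEntry("P1", "protein one", "Sm/LSm", None, "MKVLAAGERWNDFYQITHPC"),
            PanelEntry("P2", "protein two", "U1", "grpA", "MNNDEQRKLIVFWYHACGTS"),
            PanelEntry("P3", "protein three", "U2-related", "grpA", "MWWYYFFHHKKRRDDEEGGA"),
            PanelEntry("P4", "protein four", "miscellaneous", None, "MAVILMFWPGSTCYNQDEKR"),
        ]
    )


@pytest.fixture(scope="session")
def easy_bundle():
    """The packaged 'easy' scenario at seed 1, shared across test modules."""
    from spliceopanel.synthetic import build_scenario

    return build_scenario("easy", seed=1)


@pytest.fixture(scope="session")
def easy_assignment(easy_bundle):
    """RBH assignment of the easy scenario's transcripts (computed once)."""
    from spliceopanel.homology import assign_orthologues

    return assign_orthologues(
        easy_bundle.transcriptome.ngs, easy_bundle.panel, easy_bundle.decoys
    )
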