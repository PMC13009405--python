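import numpy as np
import pytest

from discourselsm import irt, synthdata
from discourselsm.transcripts import Checklist, ChecklistItem, Token, Transcript


def make_tokens(words, flags=None, phrase_ids=None):
    """Build a token tuple from plain words; flags/phrase_ids optional
    parallel sequences."""
    flags = flags or [frozenset()] * len(words)
    phrase_ids = phrase_ids or [0] * len(words)
    return tuple(
        Token(position=i, surface=w, flags=frozenset(f), phrase_id=p)
        for i, (w, f, p) in enumerate(zip(words, flags, phrase_ids))
    )


@pytest.fixture(scope="session")
def toy_checklist():
    """cookie / steal (syn: take) / fall — the worked-example checklist."""
    return Checklist(items=(
        ChecklistItem(item_id="cookie", lemma="cookie", word_class="noun",
                      length_phonemes=4, frequency=1.5, imageability=600.0),
        ChecklistItem(item_id="steal", lemma="steal", synonyms=frozenset({"take"}),
                      word_class="verb", length_phonemes=4, frequency=2.0,
                      imageability=450.0),
        ChecklistItem(item_id="fall", lemma="fall", word_class="verb",
                      length_phonemes=3, frequency=3.0, imageability=500.0),
    ), stimulus_name="toy")


@pytest.fixture(scope="session")
def rasch_matrix_17():
    """Seeded 17-item Rasch sample with no degenerate columns."""
    k = 17
    b = np.linspace(-2.0, 2.0, k)
    for seed in range(100, 200):
        rng = np.random.default_rng(seed)
        X = irt.simulate_responses(150, np.ones(k), b, rng=rng)
        m = irt.ItemResponseMatrix([f"p{i}" for i in range(150)],
                                   [f"i{j:02d}" for j in range(k)], X)
        if not m.degenerate_columns():
            return m, b
    raise RuntimeError("no non-degenerate draw found")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure synthetic cohort, desk sized for fast tests."""
    cfg = synthdata.SimulationConfig(n_participants=40, grid_shape=(20, 20, 20), seed=5)
    return synthdata.generate_cohort(cfg)
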