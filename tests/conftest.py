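import numpy as np
import pytest

from prl_qlearn import Session, SubjectMeta, TrialRecord


def build_session(
    choices,
    rewards,
    correct,
    subject_id="s01",
    group="control",
    sex="female",
    phase="pre_stress",
    session_index=1,
    reversal_index=None,
):
    """Construct a Session from per-trial sequences.

    ``choices``/``correct`` are iterables of "L"/"R"; ``rewards`` of 0/1.
    The reversal index is derived from flips of ``correct`` unless given.
    """
    choices = list(choices)
    rewards = list(rewards)
    correct = list(correct)
    assert len(choices) == len(rewards) == len(correct)
    if reversal_index is None:
        reversal_index = []
        rev = 0
        for i, c in enumerate(correct):
            if i > 0 and c != correct[i - 1]:
                rev += 1
            reversal_index.append(rev)
    meta = SubjectMeta(subject_id, group, sex, phase, session_index)
    trials = [
        TrialRecord(i + 1, ch, co, r, rv)
        for i, (ch, co, r, rv) in enumerate(zip(choices, correct, rewards, reversal_index))
    ]
    return Session(meta, trials)


def random_session(rng, n_trials=30, **meta_kwargs):
    """A structurally valid random session (choices/rewards/reversals)."""
    correct = []
    side = int(rng.integers(2))
    streak = 0
    choices = []
    rewards = []
    for _ in range(n_trials):
        c = int(rng.integers(2))
        choices.append("LR"[c])
        correct.append("LR"[side])
        rewards.append(int(rng.random() < (0.8 if c == side else 0.2)))
        if c == side:
            streak += 1
        else:
            streak = 0
        if streak >= 8:
            side = 1 - side
            streak = 0
    return build_session(choices, rewards, correct, **meta_kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_session():
    """The 6-trial hand-checked session used by the measure tests."""
    return build_session(
        choices="LLRRRL",
        rewards=[1, 0, 1, 1, 0, 0],
        correct="LLRRRR",
    )
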