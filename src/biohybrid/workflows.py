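"""High-level study workflows: session -> events/ITIs/TFIs -> statistics.

These functions glue the pipeline stages together the way the full
protocol uses them; the acceptance script and the CLI are thin callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassifierConfig, ClassificationResult, compare_iti_anova, train_and_validate
from .coherence import CoherenceConfig, micro_event_tfi
from .events import CWTConfig, compute_iti, compute_masp, detect_events
from .session import EmbodimentConfig, SessionRecord, run_session

__all__ = ["SessionAnalysis", "analyze_session", "DayResult", "run_embodiment_day",
           "child_seeds"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (kept below 2**31)."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class SessionAnalysis:
    """Events, intervals and per-event TFIs extracted from one session."""

    record: SessionRecord
    event_times: np.ndarray
    itis: np.ndarray
    tfis: list                    # TFIImage, edge-clipped events skipped
    n_skipped: int

    @property
    def labels(self) -> list:
        return [self.record.encoding] * len(self.tfis)


def analyze_session(
    record: SessionRecord,
    cwt: CWTConfig = CWTConfig(),
    coh: CoherenceConfig = CoherenceConfig(),
    with_tfis: bool = True,
) -> SessionAnalysis:
    """Run the CWT event pipeline on a session and image its events."""
    masp_eff = compute_masp(record.efferent, config=cwt,
                            electrode=record.efferent.electrode)
    events = detect_events(masp_eff, cwt)
    tfis, skipped = [], 0
    if with_tfis:
        masp_aff = compute_masp(record.afferent, config=cwt,
                                electrode=record.afferent.electrode)
        for i, t in enumerate(events):
            im = micro_event_tfi(masp_eff, masp_aff, float(t), coh,
                                 mode=record.mode, encoding=record.encoding,
                                 div_label=record.div_label, event_id=i)
            if im is None:
                skipped += 1
            else:
                tfis.append(im)
    return SessionAnalysis(record=record, event_times=events,
                           itis=compute_iti(events), tfis=tfis, n_skipped=skipped)


@dataclass
class DayResult:
    """One recording day of one embodiment mode: SA and RA sessions,
    their TFI classification and the ITI comparison."""

    div_label: str
    mode: str
    sa: SessionAnalysis
    ra: SessionAnalysis
    classification: ClassificationResult
    iti_stats: object

    @property
    def n_tfis(self) -> int:
        return len(self.sa.tfis) + len(self.ra.tfis)


def run_embodiment_day(
    mode: str,
    div: int,
    culture_seed: int,
    session_seeds: tuple,
    duration: float = 300.0,
    cwt: CWTConfig = CWTConfig(),
    coh: CoherenceConfig = CoherenceConfig(),
    clf: ClassifierConfig | None = None,
    **session_kwargs,
) -> DayResult:
    """Simulate the SA and RA sessions of one day, classify their TFIs and
    compare their inter-tap intervals."""
    analyses = {}
    for enc, s in zip(("SA", "RA"), session_seeds):
        cfg = EmbodimentConfig(mode=mode, encoding=enc, seed=s,
                               culture_seed=culture_seed, duration=duration,
                               div_label=f"DIV{21 + div}", **session_kwargs)
        analyses[enc] = analyze_session(run_session(cfg), cwt, coh)
    images = analyses["SA"].tfis + analyses["RA"].tfis
    labels = analyses["SA"].labels + analyses["RA"].labels
    if clf is None:
        clf = ClassifierConfig(seed=culture_seed)
    result = train_and_validate(images, labels, clf)
    iti = compare_iti_anova(analyses["RA"].itis, analyses["SA"].itis)
    return DayResult(div_label=f"DIV{21 + div}", mode=mode,
                     sa=analyses["SA"], ra=analyses["RA"],
                     classification=result, iti_stats=iti)
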