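"""Default definitions of the four functional reach tasks.

Every task starts near the anatomical position (arm hanging, slight elbow
flexion) and moves monotonically to its goal posture, so the range of motion
of each channel equals |end − start|.  The default end postures are the
reference-device mean angles at the point of target achieved reported for
healthy adults, and the start postures are chosen so the per-channel
excursions match the corresponding reported ranges of motion.  They are
package defaults for simulation, not measurements.
"""

from __future__ import annotations

import numpy as np

from .types import Task, TaskDefinition

# (start, end) per channel: shoulder F/E, Add/Abd, IR/ER, elbow F/E (degrees)
_DEFAULTS: dict[Task, tuple[tuple[float, ...], tuple[float, ...]]] = {
    Task.CONTRALATERAL_SHOULDER: ((-5.6, -14.7, 1.8, 27.0), (38.1, -0.4, 68.5, 125.2)),
    Task.HAND_TO_MOUTH: ((-5.0, -22.6, 3.1, 27.3), (57.3, -8.2, 32.3, 129.6)),
    Task.COMBING_HAIR: ((-3.4, -7.8, -17.5, 28.7), (102.6, -54.7, 25.3, 139.6)),
    Task.BACK_POCKET: ((-4.2, -8.8, 14.4, 29.1), (-42.9, -25.5, 37.7, 81.2)),
}

#: Default movement time, seconds (configurable; self-paced reaches take ~2 s).
DEFAULT_DURATION = 2.0


def default_task(task: Task | str, duration: float = DEFAULT_DURATION) -> TaskDefinition:
    """Return the default :class:`TaskDefinition` for one of the four tasks."""
    task = Task(task)
    start, end = _DEFAULTS[task]
    return TaskDefinition(
        task_id=task,
        start_angles=np.array(start),
        end_angles=np.array(end),
        duration=duration,
    )


def default_tasks(duration: float = DEFAULT_DURATION) -> list[TaskDefinition]:
    """All four default tasks, in protocol order."""
    return [default_task(t, duration) for t in Task]
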