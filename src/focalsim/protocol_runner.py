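"""Experiment protocols, run control, subject folders, questionnaires, logging.

A protocol is an ordered list of (scene id, parameter) pairs drawn from a
protocol pool; running one executes registered scene callables in order,
honoring a scriptable control stream of repeat/skip/restart commands (the
file-based stand-in for an experimenter's keyboard).  Every executed scene
instance writes into its own subfolder of the subject folder, and every
data file it produces is system-timestamped, so a finished run is fully
attributable offline: gaze files, tuning-power logs, questionnaire
answers, task responses.

Subject folders are created under a results root named after the user id;
a name collision appends an incremented suffix (``sub01``, ``sub01_1``,
``sub01_2``, ...) so no run ever overwrites another.

Questionnaires are JSON files named after their abbreviation (a NASA-TLX
definition ships with the package); answers are written as timestamped
CSVs of (item id, response, timestamp).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateError
from .gaze_sim_io import timestamped_path

__all__ = [
    "Protocol",
    "Questionnaire",
    "QuestionnaireItem",
    "RunState",
    "load_protocol_pool",
    "select_protocol",
    "create_subject_folder",
    "run_protocol",
    "load_questionnaire",
    "record_answers",
    "read_answers",
]


@dataclass(frozen=True)
class Protocol:
    """Named, ordered list of (scene id, parameter string); ids may repeat."""

    name: str
    scenes: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.scenes:
            raise ConfigurationError(f"protocol {self.name!r} has no scenes")


@dataclass(frozen=True)
class QuestionnaireItem:
    item_id: str
    prompt: str
    scale: Mapping


@dataclass(frozen=True)
class Questionnaire:
    abbreviation: str
    items: Tuple[QuestionnaireItem, ...]

    def __post_init__(self) -> None:
        ids = [i.item_id for i in self.items]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("questionnaire item ids must be unique")


@dataclass
class RunState:
    """Mutable cursor of an in-progress protocol run."""

    subject_id: str
    protocol: Protocol
    index: int = 0
    scene_folders: List[Path] = field(default_factory=list)


def load_protocol_pool(path) -> List[Protocol]:
    """Load all protocols from a JSON pool file.

    Accepted shapes: a top-level list of protocol objects or
    ``{"protocols": [...]}``; each protocol is
    ``{"name": ..., "scenes": [{"id": ..., "param": ...}, ...]}`` where a
    param of ``"0"`` (or absence) means no extra configuration.
    """
    raw = json.loads(Path(path).read_text())
    entries = raw["protocols"] if isinstance(raw, dict) else raw
    if not entries:
        raise ConfigurationError("protocol pool is empty")
    pool = []
    for entry in entries:
        scenes = tuple(
            (scene["id"], str(scene.get("param", "0"))) for scene in entry["scenes"]
        )
        pool.append(Protocol(name=entry["name"], scenes=scenes))
    names = [p.name for p in pool]
    if len(names) != len(set(names)):
        raise ConfigurationError("duplicate protocol names in pool")
    return pool


def select_protocol(
    pool: Sequence[Protocol],
    name: Optional[str] = None,
    seed: Optional[int] = None,
) -> Protocol:
    """Pick a protocol explicitly by name or uniformly at random (seeded)."""
    if name is not None:
        for protocol in pool:
            if protocol.name == name:
                return protocol
        raise ConfigurationError(f"no protocol named {name!r} in pool")
    rng = np.random.default_rng(seed)
    return pool[int(rng.integers(len(pool)))]


def create_subject_folder(root, user_id: str) -> Path:
    """``root/userID``; on collision ``root/userID_1``, ``_2``, ... (never overwrites)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    candidate = root / user_id
    counter = 1
    while candidate.exists():
        candidate = root / f"{user_id}_{counter}"
        counter += 1
    candidate.mkdir()
    return candidate


def _scene_folder(subject_folder: Path, index: int, scene_id: str) -> Path:
    safe = re.sub(r"[^A-Za-z0-9_.-]+", "_", scene_id)
    folder = subject_folder / f"{index + 1:02d}_{safe}"
    folder.mkdir(exist_ok=True)
    return folder


SceneCallable = Callable[[str, Path], None]


def run_protocol(
    protocol: Protocol,
    subject_folder,
    registry: Mapping[str, SceneCallable],
    controls: Optional[Sequence[Mapping]] = None,
) -> pd.DataFrame:
    """Execute the protocol's scenes in order and return the run log.

    ``registry`` maps scene ids to callables ``f(param, out_folder)``.
    ``controls`` is a scriptable control stream replacing interactive
    keyboard input: each entry ``{"scene_index": i, "action": a}`` with
    action ``skip`` (applied before scene i runs), ``repeat`` (scene i runs
    again immediately after completing, into the same subfolder), or
    ``restart`` (the run restarts from scene 0 after scene i; consumed
    once).  Unknown scene ids abort with context.
    """
    subject_folder = Path(subject_folder)
    for scene_id, _ in protocol.scenes:
        if scene_id not in registry:
            raise ConfigurationError(
                f"protocol {protocol.name!r} references unknown scene {scene_id!r}"
            )
    pending = list(controls or [])

    def take(index: int, action: str) -> bool:
        for k, cmd in enumerate(pending):
            if cmd["scene_index"] == index and cmd["action"] == action:
                del pending[k]
                return True
        return False

    log_rows = []
    order = 0
    index = 0
    while index < len(protocol.scenes):
        scene_id, param = protocol.scenes[index]
        folder = _scene_folder(subject_folder, index, scene_id)
        if take(index, "skip"):
            log_rows.append((order, index, scene_id, param, "skipped", str(folder)))
            order += 1
            index += 1
            continue
        registry[scene_id](param, folder)
        log_rows.append((order, index, scene_id, param, "run", str(folder)))
        order += 1
        while take(index, "repeat"):
            registry[scene_id](param, folder)
            log_rows.append((order, index, scene_id, param, "repeated", str(folder)))
            order += 1
        if take(index, "restart"):
            log_rows.append((order, index, scene_id, param, "restart", str(folder)))
            order += 1
            index = 0
            continue
        index += 1

    log = pd.DataFrame(
        log_rows, columns=["order", "scene_index", "scene_id", "param", "status", "folder"]
    )
    log.to_csv(timestamped_path(subject_folder, "run_log", ".csv"), index=False)
    return log


def _packaged_questionnaire_dir():
    return resources.files("focalsim").joinpath("data", "questionnaires")


def load_questionnaire(abbreviation: str, folder=None) -> Questionnaire:
    """Load ``<abbreviation>.json`` from ``folder`` (default: the packaged set)."""
    if folder is not None:
        candidates = [Path(folder) / f"{abbreviation}.json", Path(folder) / f"{abbreviation.lower()}.json"]
        for path in candidates:
            if path.exists():
                raw = json.loads(path.read_text())
                break
        else:
            raise ConfigurationError(f"no questionnaire file for {abbreviation!r} in {folder}")
    else:
        base = _packaged_questionnaire_dir()
        for name in (f"{abbreviation}.json", f"{abbreviation.lower()}.json"):
            candidate = base.joinpath(name)
            if candidate.is_file():
                raw = json.loads(candidate.read_text())
                break
        else:
            raise ConfigurationError(f"no packaged questionnaire named {abbreviation!r}")
    items = tuple(
        QuestionnaireItem(item_id=i["id"], prompt=i["prompt"], scale=i.get("scale", {}))
        for i in raw["items"]
    )
    return Questionnaire(abbreviation=raw.get("abbreviation", abbreviation), items=items)


def record_answers(questionnaire: Questionnaire, answers: Mapping[str, object], out_folder) -> Path:
    """Write answers as a timestamped CSV (item_id, response, timestamp); returns the path.

    Raises ConfigurationError for an answer keyed by an unknown item id.
    """
    known = {i.item_id for i in questionnaire.items}
    unknown = set(answers) - known
    if unknown:
        raise ConfigurationError(f"answers for unknown items: {sorted(unknown)}")
    path = timestamped_path(out_folder, f"answers_{questionnaire.abbreviation}", ".csv")
    stamp = pd.Timestamp.now().isoformat()
    frame = pd.DataFrame(
        {
            "item_id": [i.item_id for i in questionnaire.items if i.item_id in answers],
            "response": [answers[i.item_id] for i in questionnaire.items if i.item_id in answers],
            "timestamp": stamp,
        }
    )
    frame.to_csv(path, index=False)
    return path


def read_answers(path) -> Dict[str, str]:
    """Read an answers CSV back into an item_id -> response mapping."""
    frame = pd.read_csv(path, dtype=str)
    return dict(zip(frame["item_id"], frame["response"]))
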