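"""Run one experiment protocol end to end: subject folder, scenes in
order, questionnaire, and the timestamped per-scene output files.

Demonstrates the experiment-manager semantics: a protocol is an ordered
list of parameterized scenes; each executed scene writes gaze, tuning,
response or answer files into its own subfolder; re-running the same
subject id creates sub01_1 instead of overwriting.
"""

import json
import tempfile
from pathlib import Path

from focalsim import (
    EyeModel,
    GazePointController,
    create_subject_folder,
    load_protocol_pool,
    load_questionnaire,
    record_answers,
    run_block,
    run_protocol,
    select_protocol,
)

pool_spec = [
    {
        "name": "Group 1",
        "scenes": [
            {"id": "02 Experiment", "param": "1"},
            {"id": "03 Questionnaire", "param": "TLX"},
        ],
    }
]


def experiment(param, folder):
    eye = EyeModel(pupil_diameter_mm=4.0, accommodation_amplitude_D=0.0)
    run_block(3, eye, controller_factory=lambda: GazePointController(),
              seed=int(param), out_dir=folder)


def questionnaire(param, folder):
    q = load_questionnaire(param)
    record_answers(q, {item.item_id: "50" for item in q.items}, folder)


with tempfile.TemporaryDirectory() as tmp:
    pool_path = Path(tmp) / "pool.json"
    pool_path.write_text(json.dumps(pool_spec))
    pool = load_protocol_pool(pool_path)
    protocol = select_protocol(pool, seed=0)

    registry = {"02 Experiment": experiment, "03 Questionnaire": questionnaire}
    for _ in range(2):  # two sessions for the same subject id
        subject = create_subject_folder(Path(tmp) / "results", "sub01")
        log = run_protocol(protocol, subject, registry)
        print(f"subject folder: {subject.name}")
        for scene_dir in sorted(p for p in subject.iterdir() if p.is_dir()):
            files = sorted(f.name for f in scene_dir.iterdir())
            print(f"  {scene_dir.name}: {files}")
print("Each file name carries a system timestamp; a second session never overwrites the first.")
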