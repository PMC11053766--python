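"""Run matching-task blocks for an uncorrected presbyope and for the same
eye wearing a gaze-driven autofocal, and compare accuracy.

Each trial shows a Landolt ring, a Sloan letter and an 8-column lookup
table on three screens (0.30 m / 1 m / 6 m); the synthetic observer
identifies each optotype with a probability that falls with blur/gap
ratio, then answers whether the pair occupies one table column.
"""

from focalsim import EyeModel, GazePointController, TunableLens, run_block

presbyope = EyeModel(pupil_diameter_mm=4.0, accommodation_amplitude_D=0.0)
N = 40

uncorrected = run_block(N, presbyope, lens=TunableLens(current_power_D=0.0), seed=12)
autofocal = run_block(
    N, presbyope, controller_factory=lambda: GazePointController(), seed=12
)

print(f"{N}-trial blocks, absolute presbyope (accommodation amplitude 0 D):")
print(
    f"  fixed 0 D lens : accuracy {uncorrected.accuracy:.2f}, "
    f"mean RT {uncorrected.mean_reaction_time_s:.2f} s"
)
print(
    f"  ideal autofocal: accuracy {autofocal.accuracy:.2f}, "
    f"mean RT {autofocal.mean_reaction_time_s:.2f} s"
)
rec = uncorrected.records[0]
print(
    "Uncorrected, the near screen carries "
    f"{rec.defocus_D['near']:.2f} D of defocus (blur ~ pupil x defocus), so "
    "near optotypes are often misread; the autofocal nulls defocus at the gaze."
)
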