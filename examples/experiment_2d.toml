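# 2D photon-counting acquisition: 512 x 512 at ~30 fps with a resonant
# scanner (15.778 kHz bidirectional line rate) and an 80 MHz laser.
# Negative input numbers trigger on the falling edge of the signal.

rows = 512
columns = 512
planes = 1                  # 1 = 2D imaging
bidirectional = true
fill_fraction = 0.8         # central fraction of the line period rendered
line_frequency_hz = 15778.0 # 2 x mirror frequency in bidirectional mode
frame_rate_hz = 30.0        # used only with a frame_sync-only wiring
laser_period_ps = 12500     # 80 MHz pulse train
tag_frequency_hz = 189000.0 # varifocal lens (unused while planes = 1)
tag_phase0_rad = 0.0
demultiplex = false
bidir_phase_ps = 0          # odd-line window shift (line-shift correction)
rolling_window_frames = 30  # display averages the last 30 frames
filename = "run_2d"
replay_existing = false

[[channels]]
input_number = 1
role = "line_sync"
threshold = 0.25
label = "resonant line sync"

[[channels]]
input_number = 2
role = "spectral"
threshold = 0.05
label = "green PMT"

[[channels]]
input_number = -3
role = "spectral"
threshold = -0.05
label = "red PMT (falling edge)"
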