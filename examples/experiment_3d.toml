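# Continuous volumetric acquisition through a varifocal (TAG) lens
# resonating near 189 kHz. planes must be an even value > 1; the plane
# of each photon is computed from the lens phase at its arrival time.

rows = 64
columns = 64
planes = 8
bidirectional = true
fill_fraction = 0.8
line_frequency_hz = 15778.0
frame_rate_hz = 30.0
laser_period_ps = 12500
tag_frequency_hz = 189000.0
tag_phase0_rad = 0.0
demultiplex = false
bidir_phase_ps = 0
rolling_window_frames = 1
filename = "run_3d"
replay_existing = false

[[channels]]
input_number = 1
role = "line_sync"
threshold = 0.25
label = "resonant line sync"

[[channels]]
input_number = 5
role = "tag_sync"
threshold = 0.3
label = "TAG lens phase sync"

[[channels]]
input_number = 2
role = "spectral"
threshold = 0.05
label = "green PMT"
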