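# Two-beam temporal multiplexing: one excitation path is delayed by half
# the laser inter-pulse period (6.25 ns for an 80 MHz source) and the
# detected photons are gated into two demultiplexed streams by their
# arrival time relative to the last laser reference pulse.

rows = 64
columns = 64
planes = 1
bidirectional = true
fill_fraction = 0.8
line_frequency_hz = 15778.0
laser_period_ps = 12500
demultiplex = true
filename = "run_demux"

[[channels]]
input_number = 1
role = "line_sync"
threshold = 0.25
label = "resonant line sync"

[[channels]]
input_number = 4
role = "laser_sync"
threshold = 0.2
label = "laser reference pulses"

[[channels]]
input_number = 2
role = "spectral"
threshold = 0.05
label = "green PMT"
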