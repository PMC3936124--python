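# Device-chain presets. Rates in Hz, latency/jitter in ms.
# "reference" plays the RT-box role: sub-millisecond timestamps, zero delay.
# "gaming" (1000-Hz poll) and "standard" (125-Hz poll) carry fixed latencies
# calibrated so their total mean delays fall in the measured ranges of real
# configurations (roughly 5-10 ms gaming, 30-36 ms standard): the poll-rate
# difference alone (3.5 ms mean) does not explain the standard mouse's extra
# delay, which is lumped into fixed_latency_ms (click-detection logic and
# driver path).
reference:
  refresh_hz: .inf
  poll_hz: .inf
  fixed_latency_ms: 0.0
  jitter_sd_ms: 0.0
gaming:
  refresh_hz: 60.0
  poll_hz: 1000.0
  fixed_latency_ms: 6.1
  jitter_sd_ms: 1.5
standard:
  refresh_hz: 60.0
  poll_hz: 125.0
  fixed_latency_ms: 27.0
  jitter_sd_ms: 2.5
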