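"""Score a murine Multiple Sleep Latency Test (five 20-min naps).

Builds a day where the animal falls asleep progressively faster in each nap
and prints per-nap latencies (censored at 1200 s when no valid bout occurs)
and accumulated sleep.
"""

from sleeparch import Hypnogram, MSLTProtocol, mslt_score

tokens = ["W"] * 8640
proto = MSLTProtocol()  # naps at ZT2, 4, 6, 8, 10
for i, (start_s, dur_s) in enumerate(proto.nap_windows):
    e0 = int(start_s / 10)
    lat_epochs = max(0, 30 - 10 * i)  # 300 s, 200 s, 100 s, 0 s, 0 s
    for k in range(lat_epochs, 120):
        tokens[e0 + k] = "N"

res = mslt_score(Hypnogram.from_states(tokens))
print("nap | NREM latency (s) | censored | NREM (min)")
for nap in res.naps:
    print(f" {nap.nap_index}  |      {nap.latency_to_nrem_s:6.0f}      |  "
          f"{str(nap.nrem_censored):5s}   |   {nap.nrem_min:5.1f}")
print(f"\nMean NREM latency: {sum(n.latency_to_nrem_s for n in res.naps) / 5:.0f} s")
print("Shorter latencies across naps indicate greater sleep propensity; a "
      "censored nap means no two-epoch sleep bout occurred within 20 min.")
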