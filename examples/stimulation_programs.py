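"""Decode, simulate and dose an LED stimulation program.

The 1 Hz bytecode has four instructions: ON up to 127 s (0x00-0x7E), OFF up
to 127 s (0x80-0xFE), REPEAT (0x7F) and HALT (0xFF). The standard pulsed
stimulation is 5 s on / 20 s off, repeated.
"""

from optopattern import decode, dose, duty_cycle, encode, simulate

program = decode(bytes([0x04, 0x93, 0x7F]))  # ON 5 / OFF 20 / REPEAT
print("program:        ", program)
print("bytes:          ", encode(program).hex(" "))

hours = 24
duration = hours * 3600
timeline = simulate(program, duration)
print(f"duty cycle:      {duty_cycle(program, duration):.3f}")
print(f"on-time in {hours} h: {timeline.on_seconds} s")
print(f"dose @ 1 mW/s:   {dose(program, duration, power=1.0):.0f} mW*s")

# The duty cycle is the fraction of time the LED is lit (0.2 for 5/25 s
# cycles); the dose is power x on-seconds and is what couples a stimulation
# schedule to induction strength in the synthetic generator.
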