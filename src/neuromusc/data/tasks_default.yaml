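# Default task table: kinematic and timing targets for the four plyometric
# and three strength tasks (version 1).
#
# Plyometric trials last 3 s at 1000 Hz, strength repetitions 4 s at
# 1000 Hz (2 s eccentric + 2 s concentric, no pause), 10 replicates each.
# Angles in degrees (hip/knee flexion, ankle dorsiflexion); drop heights in
# m; loads as fractions of the 1RM reference moment.
tasks:
  CMJ:
    kind: plyo
    duration_s: 3.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 10.0, knee: 15.0, ankle: 5.0}
    bottom_deg: {hip: 75.0, knee: 90.0, ankle: 25.0}
    knee_bottom_range_deg: [85.0, 95.0]
    trunk_limit_deg: [10.0, 20.0]
    takeoff_velocity: 1.9
    quiet_s: 0.45
    descent_s: 0.70
  broad_jump:
    kind: plyo
    duration_s: 3.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 17.0, knee: 15.0, ankle: 5.0}   # ~7 deg initial trunk lean
    bottom_deg: {hip: 70.0, knee: 90.0, ankle: 25.0}
    knee_bottom_range_deg: [85.0, 95.0]
    trunk_limit_deg: [5.0, 10.0]
    takeoff_velocity: 1.35
    horizontal_velocity: 0.75
    quiet_s: 0.45
    descent_s: 0.70
  DJ30:
    kind: plyo
    duration_s: 3.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 10.0, knee: 15.0, ankle: 5.0}
    bottom_deg: {hip: 62.0, knee: 85.0, ankle: 24.0}
    knee_bottom_range_deg: [80.0, 100.0]
    trunk_limit_deg: [10.0, 20.0]
    drop_height_m: 0.30
    takeoff_velocity: 1.7
    platform_s: 0.40
    amortization_limit_s: 0.2
  DJ50:
    kind: plyo
    duration_s: 3.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 10.0, knee: 15.0, ankle: 5.0}
    bottom_deg: {hip: 70.0, knee: 97.0, ankle: 27.0}
    knee_bottom_range_deg: [80.0, 100.0]
    trunk_limit_deg: [10.0, 20.0]
    drop_height_m: 0.50
    takeoff_velocity: 1.8
    platform_s: 0.40
    amortization_limit_s: 0.2
  back_squat:
    kind: strength
    duration_s: 4.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 10.0, knee: 15.0, ankle: 5.0}
    bottom_deg: {hip: 95.0, knee: 105.0, ankle: 17.5}
    knee_bottom_range_deg: [100.0, 110.0]
    trunk_limit_deg: [25.0, 35.0]
    eccentric_s: 2.0
    concentric_s: 2.0
    loads: [0.75, 0.85]
    default_load: 0.85
    governing_joint: hip
    posture_1rm_deg: {hip: 60.0, knee: 90.0, ankle: 15.0}
  deadlift:
    kind: strength
    duration_s: 4.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 12.0, knee: 12.0, ankle: 4.0}
    bottom_deg: {hip: 102.5, knee: 95.0, ankle: 7.5}
    knee_bottom_range_deg: [90.0, 100.0]
    trunk_limit_deg: [35.0, 45.0]
    eccentric_s: 2.0
    concentric_s: 2.0
    loads: [0.75, 0.85]
    default_load: 0.85
    governing_joint: hip
    posture_1rm_deg: {hip: 60.0, knee: 110.0, ankle: 5.0}
  leg_press:
    kind: strength
    duration_s: 4.0
    fs_hz: 1000
    replicates: 10
    stance_deg: {hip: 10.0, knee: 12.0, ankle: 4.0}
    bottom_deg: {hip: 85.0, knee: 95.0, ankle: 12.5}
    knee_bottom_range_deg: [90.0, 100.0]
    trunk_limit_deg: [0.0, 10.0]
    eccentric_s: 2.0
    concentric_s: 2.0
    loads: [0.75, 0.85]
    default_load: 0.85
    governing_joint: hip
    posture_1rm_deg: {hip: 50.0, knee: 90.0, ankle: 10.0}
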