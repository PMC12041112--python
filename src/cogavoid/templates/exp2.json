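{
 "name": "exp2",
 "room": {
  "width": 8.0,
  "depth": 8.0,
  "height": 3.0,
  "wall_color": [
   200,
   200,
   200
  ]
 },
 "us": {
  "intensity_at_source": 80.0,
  "decay_fraction_per_meter": 0.25,
  "duration": 1.0,
  "source_position": [
   0.0,
   0.0,
   0.0
  ]
 },
 "stimuli": [
  {
   "cs_label": "CS+",
   "shape": "cube",
   "color": [
    46,
    61,
    124
   ],
   "size": [
    0.2,
    0.2,
    0.2
   ],
   "pedestal_position": [
    0.0,
    0.0,
    0.0
   ]
  },
  {
   "cs_label": "CS-",
   "shape": "cube",
   "color": [
    5,
    31,
    32
   ],
   "size": [
    0.2,
    0.2,
    0.2
   ],
   "pedestal_position": [
    0.0,
    0.0,
    0.0
   ]
  }
 ],
 "phases": [
  {
   "phase_kind": "practice",
   "n_trials_per_condition": 0,
   "reinforcement_rate": 0.0,
   "cs_duration": 0.0,
   "us_onset": null,
   "start_distance": 2.0,
   "iti_range": [
    9.0,
    15.0
   ],
   "movement_allowed": true,
   "instructed_approach": false,
   "pre_phase_us": 0,
   "free_duration": 40.0
  },
  {
   "phase_kind": "pavlovian_acquisition",
   "n_trials_per_condition": 8,
   "reinforcement_rate": 0.75,
   "cs_duration": 9.0,
   "us_onset": 8.0,
   "start_distance": 2.0,
   "iti_range": [
    9.0,
    15.0
   ],
   "movement_allowed": false,
   "instructed_approach": false,
   "pre_phase_us": 0,
   "free_duration": 0.0
  },
  {
   "phase_kind": "avoidance_learning",
   "n_trials_per_condition": 8,
   "reinforcement_rate": 0.75,
   "cs_duration": 9.0,
   "us_onset": 8.0,
   "start_distance": 1.0,
   "iti_range": [
    9.0,
    15.0
   ],
   "movement_allowed": true,
   "instructed_approach": false,
   "pre_phase_us": 0,
   "free_duration": 0.0
  },
  {
   "phase_kind": "transfer",
   "n_trials_per_condition": 2,
   "reinforcement_rate": 0.0,
   "cs_duration": 21.0,
   "us_onset": null,
   "start_distance": 2.5,
   "iti_range": [
    9.0,
    15.0
   ],
   "movement_allowed": true,
   "instructed_approach": false,
   "pre_phase_us": 0,
   "free_duration": 0.0
  },
  {
   "phase_kind": "instructed_extinction",
   "n_trials_per_condition": 8,
   "reinforcement_rate": 0.0,
   "cs_duration": 9.0,
   "us_onset": 8.0,
   "start_distance": 4.0,
   "iti_range": [
    9.0,
    15.0
   ],
   "movement_allowed": true,
   "instructed_approach": true,
   "pre_phase_us": 0,
   "free_duration": 0.0
  },
  {
   "phase_kind": "transfer",
   "n_trials_per_condition": 2,
   "reinforcement_rate": 0.0,
   "cs_duration": 21.0,
   "us_onset": null,
   "start_distance": 2.5,
   "iti_range": [
    9.0,
    15.0
   ],
   "movement_allowed": true,
   "instructed_approach": false,
   "pre_phase_us": 0,
   "free_duration": 0.0
  }
 ],
 "search_task": {
  "coin_lifetime": 1.0,
  "spawn_ellipse_width": 2.0,
  "spawn_ellipse_depth": 2.0,
  "spawn_height": 1.0,
  "ellipse_center_offset": 1.0,
  "collection_radius": 0.15
 },
 "tracker_rate": 90.0,
 "pedestal_position": [
  0.0,
  0.0,
  0.0
 ],
 "cs_height": 1.0,
 "us_visual_cue": true
}
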