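{
  "locomotion_verbs": ["run", "walk", "jump", "crawl", "skip", "march", "stride", "jog"],
  "fruits": ["apple", "banana", "pear", "grape", "peach", "plum", "cherry", "mango"],
  "vegetables": ["carrot", "potato", "onion", "spinach", "pepper", "celery", "broccoli"],
  "animals": ["dog", "cat", "horse", "rabbit", "sheep", "goat", "cow", "pig"],
  "colors": ["red", "blue", "green", "yellow", "purple", "orange", "brown", "pink"],
  "furniture": ["chair", "table", "sofa", "desk", "bed", "shelf", "stool", "bench"],
  "weather": ["rain", "snow", "wind", "fog", "hail", "sunshine", "storm", "cloud"],
  "tools": ["hammer", "saw", "wrench", "drill", "pliers", "chisel", "level"],
  "clothing": ["shirt", "pants", "jacket", "sock", "scarf", "glove", "sweater", "coat"],
  "instruments": ["piano", "violin", "drum", "flute", "guitar", "trumpet", "cello"],
  "kitchen_items": ["spoon", "fork", "knife", "plate", "bowl", "cup", "kettle", "pan"],
  "body_parts": ["arm", "leg", "hand", "foot", "elbow", "knee", "shoulder", "wrist"],
  "rest_states": ["sleep", "nap", "doze", "rest", "slumber"]
}
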