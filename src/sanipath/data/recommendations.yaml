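# Intervention-recommendation text blocks, keyed by dominant pathway.
# Structural defaults intended to be edited per deployment; wording should be
# adapted to local infrastructure, institutions, and regulations.
drinking_water: >
  Drinking water is a dominant route of fecal exposure. Prioritize protection
  and treatment of the distribution system, point-of-use treatment and safe
  storage promotion, and routine water-quality monitoring at kiosks,
  standpipes, and vendor supplies.
bathing_water: >
  Bathing water is a dominant route of fecal exposure. Investigate the safety
  of the sources most commonly used for bathing, promote use of improved
  sources, and address contamination of stored water.
surface_water: >
  Surface water is a dominant route of fecal exposure. Reduce discharge of
  untreated sewage to rivers, lakes, and ponds, post advisories at contact
  sites, and provide alternatives for laundry, play, and fishing activities.
ocean_water: >
  Ocean water is a dominant route of fecal exposure. Address sewage outfalls
  and drain discharge to beaches and advise on high-contact shoreline
  activities.
flood_water: >
  Flood water is a dominant route of fecal exposure. Improve drainage and
  fecal sludge containment to reduce flooding with sewage-contaminated water,
  and promote hygiene after unavoidable contact.
drain_water: >
  Open drains are a dominant route of fecal exposure. Prioritize covering or
  converting open sewage drains, reduce solid-waste blockage, and limit
  children's contact with drain water through caregiver outreach.
toilet_swab: >
  Public/shared toilets are a dominant route of fecal exposure. Improve
  cleaning regimes and handwashing infrastructure at facilities, and address
  surface contamination through maintenance and user-behavior campaigns.
produce: >
  Raw produce is a dominant route of fecal exposure. Address irrigation and
  market water quality, promote effective produce washing, and engage food
  safety authorities on market hygiene.
street_food: >
  Street food is a dominant route of fecal exposure. Work with vendors on
  safe food handling, water source quality, and utensil hygiene; consider
  vendor certification programs.
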