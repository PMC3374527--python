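# Default activity catalog: MET value per activity, grouped by domain.
# Swap this file out (activeq.activity_catalog.load_catalog) to use a
# different MET compendium.
occupation_scale:
  1: 1.5   # mostly sitting
  2: 2.3   # combination of sitting and standing up
  3: 3.0   # mostly standing up
  4: 4.5   # some physical activity
  5: 6.0   # heavy manual labor
activities:
  - {activity_id: walking_transportation, label: "Walking", domain: transportation, met: 4.0}
  - {activity_id: bicycling_transportation, label: "Bicycling", domain: transportation, met: 4.0}
  - {activity_id: motorcycle_scooter, label: "By motorcycle or scooter", domain: transportation, met: 2.5}
  - {activity_id: car_taxi, label: "By car or taxi", domain: transportation, met: 1.0}
  - {activity_id: bus_train_subway_boat, label: "By bus, train, subway, or boat", domain: transportation, met: 1.0}
  - {activity_id: watching_tv, label: "Watching TV/DVDs", domain: leisure, met: 1.0}
  - {activity_id: using_computer, label: "Using the computer", domain: leisure, met: 1.0}
  - {activity_id: sitting_listening_music, label: "Sitting listening to music, sewing, etc", domain: leisure, met: 1.0}
  - {activity_id: musical_instrument_active_games, label: "Playing a musical instrument or active computer games", domain: leisure, met: 2.0}
  - {activity_id: household_chores, label: "Doing household chores", domain: leisure, met: 3.0}
  - {activity_id: shopping_errands, label: "Shopping or other errands", domain: leisure, met: 2.3}
  - {activity_id: dancing, label: "Dancing", domain: leisure, met: 3.0}
  - {activity_id: walking_leisure, label: "Walking", domain: leisure, met: 3.4}
  - {activity_id: bicycling_leisure, label: "Bicycling", domain: leisure, met: 8.0}
  - {activity_id: aerobics, label: "Aerobics", domain: sport, met: 6.5}
  - {activity_id: weight_lifting, label: "Weight lifting", domain: sport, met: 6.0}
  - {activity_id: jogging_running, label: "Jogging or running", domain: sport, met: 8.0}
  - {activity_id: athletics, label: "Athletics", domain: sport, met: 6.0}
  - {activity_id: spinning, label: "Spinning", domain: sport, met: 8.5}
  - {activity_id: swimming, label: "Swimming", domain: sport, met: 6.0}
  - {activity_id: soccer_basketball_volleyball_floorball, label: "Soccer, basketball, volleyball, or floorball (floor hockey)", domain: sport, met: 6.0}
  - {activity_id: golf, label: "Golf", domain: sport, met: 4.5}
  - {activity_id: dance_class, label: "Dance class", domain: sport, met: 4.5}
  - {activity_id: horseback_riding, label: "Horseback riding", domain: sport, met: 4.0}
  - {activity_id: ice_skating_hockey_bandy, label: "Ice skating, ice hockey, or bandy", domain: sport, met: 7.0}
  - {activity_id: skiing, label: "Skiing (downhill or cross country)", domain: sport, met: 7.0}
  - {activity_id: martial_arts, label: "Martial arts", domain: sport, met: 10.0}
  - {activity_id: boxing_wrestling, label: "Boxing or wrestling", domain: sport, met: 6.0}
  - {activity_id: tennis_badminton_squash, label: "Tennis, badminton, or squash", domain: sport, met: 7.0}
  - {activity_id: table_tennis, label: "Table tennis", domain: sport, met: 4.0}
  - {activity_id: rowing_canoeing_surfing_sailing, label: "Rowing, canoeing, surfing, or sailing", domain: sport, met: 3.0}
  - {activity_id: motor_sports, label: "Motor sports", domain: sport, met: 4.0}
  - {activity_id: rock_climbing, label: "Rock climbing", domain: sport, met: 8.0}
  - {activity_id: other_sport, label: "Other", domain: sport, met: 2.5}
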