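code,label,category,subcategory,met
T01,Walking to or from work or school,transportation,commute_walk,3.5
T02,Brisk walking to transit or work,transportation,commute_walk,4.0
T03,Riding a train or subway (standing),transportation,commute_transit,2.0
T04,Riding a bus (seated),transportation,commute_transit,1.3
T05,Waiting for or transferring between trains,transportation,commute_transit,2.0
T06,Driving a car,transportation,commute_car_sitting,2.0
T07,Riding as a car passenger,transportation,commute_car_sitting,1.3
T08,Riding a motorcycle or scooter,transportation,commute_car_sitting,2.8
T09,Bicycling for transport (casual pace),transportation,cycling_transport,4.0
T10,Bicycling with cargo or child seat,transportation,cycling_transport,5.0
W01,Desk work at a computer,work,work_sitting,1.5
W02,Sitting in meetings,work,work_sitting,1.5
W03,Light office tasks while seated,work,work_sitting,1.3
W04,Driving for work (sales or delivery rounds),work,work_sitting,2.0
W05,Standing light work (reception or sales counter),work,work_standing,2.5
W06,Standing moderate work (assembly or food preparation),work,work_standing,3.0
W07,Standing work lifting light loads,work,work_standing,3.5
W08,Teaching or presenting while standing,work,work_standing,3.0
W09,Walking at work (patrol or errands),work,work_walking,3.3
W10,Walking while carrying light loads at work,work,work_walking,4.0
W11,Nursing or caregiving work,work,work_standing,3.0
W12,Construction or heavy manual labor,work,work_vigorous,5.5
W13,Farm fieldwork,work,work_vigorous,4.8
W14,Loading or moving heavy objects,work,work_vigorous,6.5
W15,Janitorial cleaning work,work,work_vigorous,3.5
W16,Warehouse picking and packing,work,work_standing,3.0
H01,Cooking or preparing meals,household,cooking,2.0
H02,Active cooking (several dishes at once),household,cooking,2.5
H03,Washing dishes,household,cooking,1.8
H04,Light tidying,household,cleaning,2.5
H05,General house cleaning (vacuuming or sweeping),household,cleaning,3.3
H06,Scrubbing floors or bathroom,household,cleaning,3.5
H07,Laundry (washing and hanging),household,housework_other,2.0
H08,Ironing,household,housework_other,1.8
H09,Grocery shopping,household,shopping,2.3
H10,Shopping for household goods,household,shopping,2.3
H11,Playing with children (light or seated),household,childcare,2.5
H12,Child care (bathing or feeding or carrying),household,childcare,3.0
H13,Active play with children,household,childcare,3.5
H14,Walking with a stroller or small child,household,childcare,3.0
H15,Gardening and yard work,household,car_wash_gardening,4.0
H16,Watering plants,household,car_wash_gardening,2.5
H17,Washing the car,household,car_wash_gardening,3.5
H18,Home repairs,household,housework_other,3.0
H19,Pet care (feeding or grooming),household,housework_other,2.3
H20,Walking the dog,household,housework_other,3.0
L01,Watching television,leisure_sports,screen,1.0
L02,Using a computer or the Internet,leisure_sports,screen,1.5
L03,Playing video games,leisure_sports,screen,1.5
L04,Reading,leisure_sports,quiet_leisure,1.3
L05,Listening to music,leisure_sports,quiet_leisure,1.3
L06,Talking on the phone,leisure_sports,quiet_leisure,1.3
L07,Chatting with family or friends,leisure_sports,social,1.5
L08,Hobby crafts (knitting or models),leisure_sports,hobby,1.8
L09,Playing a musical instrument,leisure_sports,hobby,2.0
L10,Board or card games,leisure_sports,hobby,1.5
L11,Relaxing or doing nothing,leisure_sports,quiet_leisure,1.0
L12,Eating out with friends,leisure_sports,social,1.5
L13,Attending a class or lecture,leisure_sports,quiet_leisure,1.5
L14,Karaoke,leisure_sports,social,2.0
L15,Visiting a cafe or bar,leisure_sports,social,1.5
L16,Strolling or window shopping,leisure_sports,leisure_walk,2.5
L17,Walking for exercise,leisure_sports,sport_exercise,3.5
L18,Brisk walking for exercise,leisure_sports,sport_exercise,4.3
L19,Jogging,leisure_sports,sport_exercise,7.0
L20,Running,leisure_sports,sport_exercise,8.3
L21,Cycling for exercise,leisure_sports,sport_exercise,6.8
L22,Swimming laps,leisure_sports,sport_exercise,6.0
L23,Golf (walking the course),leisure_sports,sport_exercise,4.8
L24,Golf practice range,leisure_sports,sport_exercise,3.0
L25,Tennis,leisure_sports,sport_exercise,7.3
L26,Badminton,leisure_sports,sport_exercise,5.5
L27,Table tennis,leisure_sports,sport_exercise,4.0
L28,Soccer or futsal,leisure_sports,sport_exercise,7.0
L29,Baseball or softball,leisure_sports,sport_exercise,5.0
L30,Basketball,leisure_sports,sport_exercise,6.5
L31,Volleyball,leisure_sports,sport_exercise,4.0
L32,Hiking,leisure_sports,sport_exercise,6.0
L33,Strength training with weights,leisure_sports,sport_exercise,3.5
L34,Calisthenics or radio exercises,leisure_sports,sport_exercise,3.5
L35,Yoga or stretching,leisure_sports,sport_exercise,2.5
L36,Pilates,leisure_sports,sport_exercise,3.0
L37,Dancing,leisure_sports,sport_exercise,4.5
L38,Martial arts,leisure_sports,sport_exercise,5.3
L39,Bowling,leisure_sports,sport_exercise,3.0
L40,Fishing,leisure_sports,outdoor_leisure,2.5
L41,Picnic or park outing,leisure_sports,outdoor_leisure,2.5
L42,Watching sports at a venue,leisure_sports,social,1.5
L43,Going to a movie theater,leisure_sports,quiet_leisure,1.0
L44,Gateball or croquet,leisure_sports,sport_exercise,3.3
L45,Skiing or snowboarding,leisure_sports,sport_exercise,5.3
U01,Sleeping,uncategorized,sleep,0.9
U02,Eating a meal,uncategorized,personal_care,1.5
U03,Washing and grooming,uncategorized,personal_care,2.0
U04,Bathing,uncategorized,personal_care,1.5
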