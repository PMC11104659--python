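group,category,terms
location,home,home;house;bed;kitchen;living room
location,university/school,uni;college;school;campus;classroom
location,work,work;working;wfh;worked;job;office;coworkers;shift
location,restaurant/bar,restaurant;bar;cocktail;menu;server;waitress
location,party,party;festivity;gathering;wedding;reunion
location,workout,workout;gym;exercise;routine;crossfit;cardio;jog;yoga;fitness
location,supermarket,supermarket;aisle;grocery;store;checkout;cashier;cart;walgreens;711;deli;walmart
location,airport,airport;layover;flight;plane;airline;delay
emotion,anxious/worried,anxious;sad;antsy;panicky;restless;tense
emotion,sad,sad;lonely;depressed;disappointed;hopeless;cry
emotion,stressed,stress;overwhelmed;overworked;unsettled;workload
emotion,tired,tired;exhausted;sick;frazzled;sluggish;drained;groggy
emotion,frustrated/angry,frustrated;irritated;snapping;pissy;mad;cranky;grumpy;ugh
emotion,happy,happy;excited;amazing;awesome;enjoying;grateful
emotion,proud,proud;accomplished;milestone;longest
emotion,bored,bored;boredom;boring;unmotivated;monotony
social,alone,alone;isolated;lonely;cooped;quarantining
social,friend(s),friend;buddy;pregaming;groomsman;friendsgiving;bros
social,family,family;parent;dad;brother;mother;wife;sister;mom
social,partner,partner;girlfriend;husband;boyfriend;wife;ex;bf
social,colleague(s),colleague;coworkers;manager;networking;boss;meetups;supervisor
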