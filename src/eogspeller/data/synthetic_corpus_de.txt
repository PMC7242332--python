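# Synthetic German fixture corpus for the word predictor.
# Stands in for a large general German corpus, which is not redistributed
# here; sentences are short everyday phrases with deliberately skewed
# word frequencies so that the half-sum proposal threshold fires on
# common continuations. Lines starting with '#' are comments and are
# skipped by the corpus loader. Keep this file small.
Ich bin hier. Ich bin hier. Ich bin hier. Ich bin hier.
Ich bin hier. Ich bin hier. Ich bin hier. Ich bin hier.
Ich bin müde. Ich bin glücklich. Ich bin zufrieden.
Ich bin heute sehr glücklich. Ich bin bei dir.
Ich möchte schlafen. Ich möchte Musik hören. Ich möchte nach Hause.
Ich möchte schlafen. Ich möchte schlafen. Ich möchte schlafen.
Ich habe dich lieb. Ich habe Durst. Ich habe keine Schmerzen.
Ich habe dich lieb. Ich habe dich lieb. Ich habe dich lieb.
Ich danke dir. Ich danke euch allen. Ich danke dir sehr.
Ich freue mich auf den Urlaub. Ich freue mich auf morgen.
Ich freue mich auf den Besuch. Ich freue mich sehr.
Du bist hier. Du bist lieb. Du bist mein Freund.
Wir sind zusammen. Wir sind eine Familie. Wir sind glücklich.
Das ist schön. Das ist gut. Das ist sehr schön. Das ist mein Haus.
Die Straße ist leer. Die Straße ist lang. Die Straße ist nass.
Der Garten ist grün. Der Garten ist schön. Der Himmel ist blau.
Meine Familie ist hier. Meine Familie ist bei mir.
Meine Enkelkinder wachsen auf. Meine Enkelkinder sind hier.
Mein Bruder kommt morgen. Meine Schwester kommt heute.
Heute ist ein schöner Tag. Heute ist ein guter Tag.
Morgen kommt der Arzt. Morgen kommt die Familie.
Bitte öffne das Fenster. Bitte schließe die Tür. Bitte hilf mir.
Danke für alles. Danke für deine Hilfe. Danke für den Besuch.
Die Musik ist schön. Die Musik ist laut. Die Musik ist leise.
Hallo zusammen. Hallo Mutter. Hallo Vater. Hallo Anna.
Guten Morgen. Guten Abend. Gute Nacht. Guten Appetit.
Es geht mir gut. Es geht mir heute gut. Es geht mir besser.
Mir ist warm. Mir ist kalt. Mir ist langweilig.
Der Müller wohnt nebenan. Der Müller ist freundlich.
Das Mädchen spielt im Garten. Das Mädchen singt schön.
Die Vögel singen draußen. Die Vögel singen am Morgen.
Ich höre gerne Musik. Ich höre gerne Radio. Ich höre dir zu.
Ich sehe den Garten. Ich sehe die Vögel. Ich sehe dich gerne.
Ich liebe dich. Ich liebe meine Familie. Ich liebe den Sommer.
Ich liebe dich. Ich liebe dich. Ich liebe dich.
Der Sommer ist warm. Der Winter ist kalt. Der Frühling ist schön.
Ein schönes Lied. Ein schöner Tag. Ein gutes Buch.
Wann kommt der Besuch. Wann kommt der Arzt. Wann gibt es Essen.
Ja bitte. Nein danke. Ja gerne. Nein nicht jetzt.
Ich bin froh. Ich bin froh. Ich bin wach. Ich bin bereit.
Ich will fernsehen. Ich will nach draußen. Ich will schlafen.
Alles ist gut. Alles wird gut. Alles ist in Ordnung.
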